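"""Synthetic data with known ground truth for the full turnover pipeline.

Three generators, all driven by one :class:`SyntheticScenario`:

* per-condition bound-probe trajectories (closed-form kinetics + Gaussian
  trace noise),
* time-lapse fields of textured elliptical cells whose integrated probe
  intensity follows those trajectories over a dim background (the probe's
  >100-fold fluorogenic contrast caps the background at 1% of initial cell
  brightness),
* dual-channel (SA + phalloidin + nuclei) single-cell populations whose
  intensity-balance and texture divergence between conditions grows with a
  per-timepoint effect-size schedule; SA and Ph intensities are
  anticorrelated across the per-cell turnover latent, mirroring the
  competing-probe logic.

Scenario presets mirror the study designs: cytoskeletal drugs, serum
switch, lineage induction (dissociation and association), media switch,
passage comparison, and a null (identical-condition) control.  Everything
is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hcia import DualChannelCellImage
from .kinetics import (
    KineticParameters,
    association_curve,
    dissociation_curve,
)
from .quantify import IntensityTrace

__all__ = [
    "ConditionSpec",
    "SyntheticScenario",
    "PRESETS",
    "preset",
    "condition_trajectory",
    "generate_traces",
    "generate_timelapse_stack",
    "generate_dual_stain_population",
    "generate_segmentation_field",
]


@dataclass(frozen=True)
class ConditionSpec:
    """Ground-truth kinetics (and optional media switch) for one condition.

    ``latent`` is the condition's unit displacement direction in the 2-D
    phenotype latent space (intensity balance, texture coarseness) used by
    the dual-stain generator; the effect-size schedule scales it.
    """

    params: KineticParameters
    switch_time: float | None = None
    post_params: KineticParameters | None = None
    latent: tuple = (0.0, 0.0)

    def __post_init__(self):
        if (self.switch_time is None) != (self.post_params is None):
            raise ValueError("switch_time and post_params must be given together")
        if self.switch_time is not None and self.switch_time <= 0:
            raise ValueError("switch_time must be positive")


@dataclass
class SyntheticScenario:
    """Full specification of a synthetic study; the generators' only input."""

    name: str
    conditions: dict
    times: np.ndarray
    mode: str = "dissociation"          # trajectory mode for traces/stacks
    noise_sd: float = 0.02              # additive Gaussian sd on C(t)
    n_replicates: int = 3
    n_fields: int = 4
    # time-lapse rendering
    frame_shape: tuple = (512, 512)
    cells_per_field: int = 30
    cell_radius_range: tuple = (8.0, 14.0)
    background_fraction: float = 0.01   # <= 1/100 of initial cell brightness
    cell_peak: float = 2000.0
    # dual-stain rendering
    divergence_schedule: dict = dc_field(default_factory=dict)
    hcia_frame_shape: tuple = (320, 320)
    hcia_cells_per_field: int = 9
    hcia_fields_per_condition: int = 8
    hcia_cell_radius_range: tuple = (16.0, 26.0)
    seed: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if not self.conditions:
            raise ValueError("scenario needs at least one condition")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for k in ("n_replicates", "n_fields", "cells_per_field",
                  "hcia_cells_per_field", "hcia_fields_per_condition"):
            if getattr(self, k) < 1:
                raise ValueError(f"{k} must be >= 1")
        if self.mode not in ("dissociation", "association"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def with_(self, **kwargs) -> "SyntheticScenario":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def condition_trajectory(spec: ConditionSpec, times: np.ndarray,
                         mode: str = "dissociation") -> np.ndarray:
    """Noise-free C(t) for a condition, honoring a mid-course parameter switch.

    At a switch the signal is continuous: the post-switch branch restarts the
    closed form from C(switch) with the new parameters.
    """
    times = np.asarray(times, dtype=float)
    p = spec.params

    def solve(par, t, c_start):
        if mode == "dissociation":
            return dissociation_curve(par.kf_d, par.kr, c_start, t)
        return association_curve(par.kf_d, par.kr, par.L_T, c_start, t)

    c_start = p.C0 if mode == "dissociation" else 0.0
    if spec.switch_time is None:
        return solve(p, times, c_start)
    pre = times <= spec.switch_time
    out = np.empty_like(times)
    out[pre] = solve(p, times[pre], c_start)
    c_sw = float(solve(p, np.array([spec.switch_time]), c_start)[0])
    post = spec.post_params
    if mode == "dissociation":
        # re-anchor: decay toward the new plateau from the switch value
        k = post.kf_d + post.kr
        if k == 0:
            out[~pre] = c_sw
        else:
            c_inf = post.kf_d * post.C0 / k
            out[~pre] = c_inf + (c_sw - c_inf) * np.exp(
                -k * (times[~pre] - spec.switch_time))
    else:
        out[~pre] = association_curve(
            post.kf_d, post.kr, post.L_T, c_sw, times[~pre] - spec.switch_time)
    return out


def generate_traces(scn: SyntheticScenario) -> list:
    """Per condition x replicate x field noisy bound-probe traces."""
    rng = np.random.default_rng([scn.seed, 0])
    traces = []
    for cond in sorted(scn.conditions):  # canonical order: seed-stable
        clean = condition_trajectory(scn.conditions[cond], scn.times, scn.mode)
        for rep in range(scn.n_replicates):
            for fld in range(scn.n_fields):
                noisy = clean + rng.normal(0.0, scn.noise_sd, size=clean.shape)
                traces.append(IntensityTrace(
                    cond, rep, fld, scn.times, np.clip(noisy, 0.0, None)))
    return traces


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _grid_positions(rng, shape, n_cells, pitch, jitter):
    h, w = shape
    margin = pitch / 2
    xs = np.arange(margin, w - margin + 1e-9, pitch)
    ys = np.arange(margin, h - margin + 1e-9, pitch)
    if len(xs) * len(ys) < n_cells:
        raise ValueError(
            f"{n_cells} cells exceed packing capacity "
            f"({len(xs) * len(ys)}) for frame {shape} at pitch {pitch:.0f}"
        )
    grid = [(y, x) for y in ys for x in xs]
    idx = rng.choice(len(grid), size=n_cells, replace=False)
    pos = np.array([grid[i] for i in idx], dtype=float)
    pos += rng.uniform(-jitter, jitter, size=pos.shape)
    return pos


def _paint_cell(canvas, cy, cx, sig_u, sig_v, angle, peak,
                stripe_wavelength, stripe_amp, stripe_phase):
    """Add one anisotropic-Gaussian cell with oriented stripe texture."""
    h, w = canvas.shape
    r = 3.0 * max(sig_u, sig_v)
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 1, h)
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = np.cos(angle) * dx + np.sin(angle) * dy
    v = -np.sin(angle) * dx + np.cos(angle) * dy
    q = (u / sig_u) ** 2 + (v / sig_v) ** 2
    body = np.where(q <= 9.0, np.exp(-0.5 * q), 0.0)
    stripes = 1.0 + stripe_amp * np.cos(
        2.0 * np.pi * v / stripe_wavelength + stripe_phase)
    canvas[y0:y1, x0:x1] += peak * body * stripes


def _render_probe_field(rng, scn: SyntheticScenario) -> np.ndarray:
    """Base scene for one time-lapse field: cells at full brightness."""
    base = np.zeros(scn.frame_shape, dtype=float)
    rmin, rmax = scn.cell_radius_range
    pos = _grid_positions(rng, scn.frame_shape, scn.cells_per_field,
                          pitch=2 * rmax + 6, jitter=3.0)
    for cy, cx in pos:
        a = rng.uniform(rmin, rmax)
        b = a * rng.uniform(0.45, 0.9)
        _paint_cell(
            base, cy, cx, sig_u=a / 2, sig_v=b / 2,
            angle=rng.uniform(0, np.pi),
            peak=scn.cell_peak * rng.lognormal(0.0, 0.15),
            stripe_wavelength=rng.uniform(5.0, 9.0),
            stripe_amp=0.4, stripe_phase=rng.uniform(0, 2 * np.pi),
        )
    return base


# ---------------------------------------------------------------------------
# time-lapse stacks
# ---------------------------------------------------------------------------

def generate_timelapse_stack(scn: SyntheticScenario, outdir) -> pd.DataFrame:
    """Render and write per-field multi-page TIFF stacks plus manifests.

    Frame k of a field is ``base * C(t_k) * (1 + eps_k) + background`` with
    Poisson shot noise, eps_k ~ N(0, noise_sd) a field-level illumination
    fluctuation, and the washed-out-probe background at
    ``background_fraction`` of the mean initial field intensity — two orders
    of magnitude below per-pixel cell brightness, honoring the probe's
    >100-fold fluorogenic contrast.  Writes
    ``manifest.csv`` (path, condition, replicate, field, times_min) and
    ``ground_truth.csv`` (the generating C(t) and scene statistics), and
    returns the manifest frame.
    """
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([scn.seed, 1])
    times_str = ";".join(f"{t:g}" for t in scn.times)
    manifest_rows, truth_rows = [], []
    for cond in sorted(scn.conditions):
        clean = condition_trajectory(scn.conditions[cond], scn.times, scn.mode)
        for rep in range(scn.n_replicates):
            for fld in range(scn.n_fields):
                base = _render_probe_field(rng, scn)
                bg = scn.background_fraction * float(base.mean())
                eps = rng.normal(0.0, scn.noise_sd, size=len(scn.times))
                pages = []
                for k, c in enumerate(clean):
                    scale = max(c * (1.0 + eps[k]), 0.0)
                    expected = base * scale + bg
                    frame = rng.poisson(expected).astype(np.uint16)
                    pages.append(frame)
                    truth_rows.append((cond, rep, fld, scn.times[k], c,
                                       float(scale), float(base.mean()), bg))
                fname = f"{cond}_r{rep}_f{fld}.tif"
                tifffile.imwrite(outdir / fname, np.stack(pages),
                                 photometric="minisblack")
                manifest_rows.append((fname, cond, rep, fld, times_str))
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["path", "condition", "replicate", "field", "times_min"])
    manifest.to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(
        truth_rows,
        columns=["condition", "replicate", "field", "time_min", "true_c",
                 "rendered_scale", "base_mean", "background"],
    ).to_csv(outdir / "ground_truth.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# dual-stain single-cell populations
# ---------------------------------------------------------------------------

_LATENT_GAIN = 0.8       # latent -> tanh saturation gain
_BALANCE_SPAN = 0.30     # max fractional SA/Ph intensity shift
_STRIPE_SPAN = 0.35      # max fractional stripe-wavelength shift


def _render_dual_field(rng, scn: SyntheticScenario, latents,
                       positions=None) -> tuple:
    """Render one 3-channel field; returns (image, per-cell truth rows).

    ``latents`` is (n_cells, 2): axis 0 shifts the SA/Ph intensity balance
    (SA up, Ph down — the competing probes), axis 1 the stripe coarseness.
    """
    shape = scn.hcia_frame_shape
    rmin, rmax = scn.hcia_cell_radius_range
    n = len(latents)
    if positions is None:
        positions = _grid_positions(rng, shape, n, pitch=2 * rmax + 10,
                                    jitter=4.0)
    sa = np.zeros(shape)
    ph = np.zeros(shape)
    nuc = np.zeros(shape)
    truth = []
    for (cy, cx), (z1, z2) in zip(positions, latents):
        a = rng.uniform(rmin, rmax)
        b = a * rng.uniform(0.5, 0.9)
        angle = rng.uniform(0, np.pi)
        balance = _BALANCE_SPAN * np.tanh(_LATENT_GAIN * z1)
        wavelength = 9.0 * (1.0 + _STRIPE_SPAN * np.tanh(_LATENT_GAIN * z2))
        sa_peak = 800.0 * (1.0 + balance) * rng.lognormal(0.0, 0.10)
        ph_peak = 800.0 * (1.0 - balance) * rng.lognormal(0.0, 0.10)
        phase = rng.uniform(0, 2 * np.pi)
        _paint_cell(sa, cy, cx, a / 2, b / 2, angle, sa_peak,
                    wavelength, 0.45, phase)
        # Ph highlights the vacated sites: same filament geometry,
        # antiphase stripe pattern
        _paint_cell(ph, cy, cx, a / 2, b / 2, angle, ph_peak,
                    wavelength, 0.45, phase + np.pi)
        nr = rng.uniform(4.0, 6.0)
        _paint_cell(nuc, cy, cx, nr, nr, 0.0, 600.0, 1e9, 0.0, 0.0)
        truth.append((cy, cx, z1, z2, sa_peak, ph_peak, wavelength))
    img = DualChannelCellImage(
        sa=rng.poisson(sa + 4.0).astype(float),
        ph=rng.poisson(ph + 4.0).astype(float),
        nuc=rng.poisson(nuc + 4.0).astype(float),
    )
    return img, truth


def generate_dual_stain_population(scn: SyntheticScenario, timepoint,
                                   outdir=None) -> tuple:
    """Dual-stain fields per condition at one pseudo-timepoint.

    The condition's latent direction is scaled by the schedule's effect size
    at ``timepoint``; per-cell latents add unit isotropic Gaussian scatter.
    Returns ``(fields, truth)`` where ``fields`` is a list of
    ``(DualChannelCellImage, condition)`` and ``truth`` a per-cell frame.
    Optionally writes 3-page TIFFs plus manifest and ground-truth CSVs.
    """
    if timepoint not in scn.divergence_schedule:
        raise ValueError(
            f"timepoint {timepoint!r} not in divergence schedule "
            f"{sorted(scn.divergence_schedule)}"
        )
    effect = scn.divergence_schedule[timepoint]
    tp_index = sorted(scn.divergence_schedule).index(timepoint)
    rng = np.random.default_rng([scn.seed, 2, tp_index])

    fields, truth_rows = [], []
    for cond in sorted(scn.conditions):
        direction = np.asarray(scn.conditions[cond].latent, dtype=float)
        for fld in range(scn.hcia_fields_per_condition):
            n = scn.hcia_cells_per_field
            latents = effect * direction + rng.normal(0.0, 1.0, size=(n, 2))
            img, truth = _render_dual_field(rng, scn, latents)
            fields.append((img, cond))
            for i, row in enumerate(truth):
                truth_rows.append((cond, fld, i, *row))
    truth = pd.DataFrame(
        truth_rows,
        columns=["condition", "field", "cell", "y", "x", "latent_balance",
                 "latent_texture", "sa_peak", "ph_peak", "stripe_wavelength"])

    if outdir is not None:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        counters: dict[str, int] = {}
        for img, cond in fields:
            fld = counters.get(cond, 0)
            counters[cond] = fld + 1
            fname = f"{cond}_tp{tp_index}_f{fld}.tif"
            stack = np.stack([img.sa, img.ph, img.nuc]).astype(np.uint16)
            tifffile.imwrite(outdir / fname, stack, photometric="minisblack")
            rows.append((fname, cond, fld, "sa;ph;nuc", str(timepoint)))
        pd.DataFrame(rows, columns=["path", "condition", "field",
                                    "channel_order", "timepoint"]
                     ).to_csv(outdir / "manifest.csv", index=False)
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    return fields, truth


def generate_segmentation_field(scn: SyntheticScenario, n_cells: int,
                                touching_pairs: int = 0,
                                seed_offset: int = 0) -> tuple:
    """One dual-stain field with a known cell count for segmentation checks.

    ``touching_pairs`` of the cells are placed as overlapping pairs (center
    separation ~85% of the summed radii) with distinct nuclei, so splitting
    them requires the seeded watershed.  Returns ``(image, true_count)``.
    """
    if touching_pairs * 2 > n_cells:
        raise ValueError("touching_pairs exceeds the requested cell count")
    rng = np.random.default_rng([scn.seed, 3, seed_offset])
    rmin, rmax = scn.hcia_cell_radius_range
    n_anchor = n_cells - touching_pairs
    anchors = _grid_positions(rng, scn.hcia_frame_shape, n_anchor,
                              pitch=2 * rmax + 14, jitter=3.0)
    positions = list(anchors)
    for k in range(touching_pairs):
        cy, cx = anchors[k]
        theta = rng.uniform(0, 2 * np.pi)
        sep = 0.85 * (rmin + rmax)
        positions.append((cy + sep * np.sin(theta), cx + sep * np.cos(theta)))
    positions = np.asarray(positions)
    latents = rng.normal(0.0, 1.0, size=(n_cells, 2))
    img, _ = _render_dual_field(rng, scn, latents, positions=positions)
    return img, n_cells


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _kp(kf_d, kr, l_t=1.0):
    return KineticParameters(kf_d=kf_d, kr=kr, L_T=l_t)


def _lineage_conditions():
    # retained late-time signal C_inf = kf_d/(kf_d+kr): AD > CH > OS ~ BA,
    # turnover index kr/kf_d: AD < CH < OS <= BA
    return {
        "BA": ConditionSpec(_kp(0.003, 0.030), latent=(0.0, 0.0)),
        "AD": ConditionSpec(_kp(0.010, 0.010), latent=(1.0, 0.0)),
        "OS": ConditionSpec(_kp(0.003, 0.027), latent=(-0.5, 0.866)),
        "CH": ConditionSpec(_kp(0.006, 0.018), latent=(-0.5, -0.866)),
    }


def preset(name: str, seed: int = 0, **overrides) -> SyntheticScenario:
    """Named study designs; any scenario field can be overridden."""
    if name == "lineage":
        scn = SyntheticScenario(
            name="lineage",
            conditions=_lineage_conditions(),
            times=np.arange(16) * 60.0,           # ~15 h induction
            divergence_schedule={"1h": 0.5, "8h": 1.25, "24h": 2.5},
            seed=seed,
        )
    elif name == "lineage_association":
        scn = SyntheticScenario(
            name="lineage_association",
            conditions=_lineage_conditions(),
            times=np.arange(13) * 30.0,
            mode="association",
            seed=seed,
        )
    elif name == "drugs":
        scn = SyntheticScenario(
            name="drugs",
            conditions={
                "UNT": ConditionSpec(_kp(0.004, 0.028)),
                "CYTO": ConditionSpec(_kp(0.009, 0.012)),
                "JASP": ConditionSpec(_kp(0.004, 0.028)),
                "NOC": ConditionSpec(_kp(0.004, 0.028)),
            },
            times=np.arange(0.0, 135.0, 15.0),
            seed=seed,
        )
    elif name == "serum":
        ba, sdm = _kp(0.004, 0.028), _kp(0.010, 0.012)
        scn = SyntheticScenario(
            name="serum",
            conditions={
                "BA": ConditionSpec(ba),
                "SDM": ConditionSpec(sdm),
                "BA>SDM": ConditionSpec(ba, switch_time=30.0, post_params=sdm),
                "SDM>BA": ConditionSpec(sdm, switch_time=30.0, post_params=ba),
            },
            times=np.arange(0.0, 135.0, 15.0),
            seed=seed,
        )
    elif name == "switch":
        ba, ad = _kp(0.003, 0.030), _kp(0.010, 0.010)
        scn = SyntheticScenario(
            name="switch",
            conditions={
                "BA": ConditionSpec(ba),
                "AD": ConditionSpec(ad),
                "BA>AD": ConditionSpec(ba, switch_time=240.0, post_params=ad),
                "AD>BA": ConditionSpec(ad, switch_time=240.0, post_params=ba),
            },
            times=np.arange(0.0, 510.0, 30.0),
            seed=seed,
        )
    elif name == "passage":
        scn = SyntheticScenario(
            name="passage",
            conditions={
                "P5": ConditionSpec(_kp(0.004, 0.028)),
                "P12": ConditionSpec(_kp(0.008, 0.014)),
            },
            times=np.arange(0.0, 97.5, 7.5),
            seed=seed,
        )
    elif name == "null":
        same = _kp(0.005, 0.025)
        scn = SyntheticScenario(
            name="null",
            conditions={
                "A": ConditionSpec(same, latent=(0.0, 0.0)),
                "B": ConditionSpec(same, latent=(0.0, 0.0)),
            },
            times=np.arange(0.0, 135.0, 15.0),
            divergence_schedule={"t0": 0.0},
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return scn.with_(**overrides) if overrides else scn


PRESETS = ("lineage", "lineage_association", "drugs", "serum", "switch",
           "passage", "null")
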