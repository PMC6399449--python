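"""Synthetic synchronized-population time courses for cyclin-knockout strains.

After release from alpha-factor arrest, a synchronized budding-yeast culture
expresses cell-cycle genes as decaying cosines on the log2 scale: the
population-level amplitude attenuates as individual cells drift out of phase.
This module generates read-count matrices, transcription-factor target
networks, reference periodic gene sets and bud-count tables with that
structure, for the wild type and the six viable cyclin single/double
knockouts, with and without osmotic stress. The strain presets carry the
generating period, onset delay, phase-duration schedule and MBF-to-SBF regulon
offset for each strain, so that a recovery of these values by the analysis
modules is a genuine round trip.

Generating model for a periodic gene (log2 scale around its mean level m)::

    f(t) = A * exp(-sigma * t) * cos(2*pi * (t - phi - onset) / period)

Expected reads are ``m * 2**f(t)``; observed counts are Poisson draws around
that expectation, optionally inflated by multiplicative lognormal noise with
coefficient of variation ``noise_cv``. Alpha-factor-response genes decay as
``m * (1 + R * 2**(-t/halflife))`` and background genes are flat.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

STRAIN_NAMES = (
    "WT",
    "cln1d",
    "cln2d",
    "cln3d",
    "cln1d_cln2d",
    "cln1d_cln3d",
    "cln2d_cln3d",
)

#: periodic gene classes recognised by the generator
PERIODIC_CLASSES = tuple(f"oscillating-cluster-{i}" for i in range(1, 6)) + (
    "MBF-target",
    "SBF-target",
)

#: default noise / attenuation used by all presets
DEFAULT_NOISE_CV = 0.2
DEFAULT_SYNCHRONY_DECAY = 0.004  # per minute; two cycles stay visible in 150 min
DEFAULT_ALPHA_HALFLIFE = 30.0  # minutes

#: ordered classification-set TF groups (phase-transition markers).
#: G1/S and M/G1 memberships follow the canonical factors; the S/G2 and
#: G2/M groups are synthetic stand-ins for the unavailable classification set.
CLASSIFICATION_GROUPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("G1/S", ("SWI4", "SWI6", "MBP1")),
    ("S/G2", ("HCM1", "YHP1")),
    ("G2/M", ("NDD1", "FKH2")),
    ("M/G1", ("MCM1", "ACE2", "SWI5")),
)


@dataclass(frozen=True)
class StrainPreset:
    """Generating parameters of one simulated strain/condition."""

    name: str
    stressed: bool
    period_min: float
    onset_delay_min: float
    phase_schedule: tuple[float, float, float]  # G1, S, G2M durations (min)
    regulon_offset_min: float  # SBF peak lag after MBF peak (min)
    alpha_decay_halflife_min: float
    oscillation_enabled: bool
    noise_cv: float
    synchrony_decay_per_min: float

    def __post_init__(self) -> None:
        if self.period_min <= 0:
            raise ValueError("period_min must be positive")
        sched = tuple(float(x) for x in self.phase_schedule)
        if len(sched) != 3 or any(x <= 0 for x in sched):
            raise ValueError("phase_schedule needs three positive durations")
        if not math.isclose(sum(sched), self.period_min, abs_tol=1e-6):
            raise ValueError("phase_schedule durations must sum to period_min")
        if not (0 <= self.regulon_offset_min < self.period_min):
            raise ValueError("regulon_offset_min must lie in [0, period_min)")

    def phase_boundaries(self) -> dict[str, float]:
        """Generating phase-transition times (min, first cycle, incl. onset).

        G2/M is placed mid-way through the merged G2M block; the block's
        duration is still read off as M/G1 minus S/G2.
        """
        g1, s, g2m = self.phase_schedule
        base = self.onset_delay_min
        return {
            "G1/S": base + g1,
            "S/G2": base + g1 + s,
            "G2/M": base + g1 + s + 0.5 * g2m,
            "M/G1": base + g1 + s + g2m,
        }


@dataclass(frozen=True)
class GeneSpec:
    """Generating parameters of one simulated gene.

    ``phi_true`` is NaN for the background and alpha-response classes. For
    the alpha-response class ``amplitude_true`` holds the induction ratio R.
    """

    gene_id: str
    gene_class: str
    phi_true: float
    amplitude_true: float
    mean_level_true: float


# strain-specific values; anything unset falls back to the wild type
_BASE = dict(
    period_min=64.0,
    onset_delay_min=0.0,
    phase_schedule=(14.0, 20.0, 30.0),
    regulon_offset_min=6.0,
    oscillation_enabled=True,
)
_STRAIN_OVERRIDES: dict[str, dict] = {
    "WT": {},
    "cln1d": {"phase_schedule": (12.3, 20.2, 31.5)},
    "cln2d": {"regulon_offset_min": 8.0},
    "cln3d": {"onset_delay_min": 5.0, "regulon_offset_min": 3.0},
    "cln1d_cln2d": {
        "period_min": 80.0,
        "phase_schedule": (12.3, 19.7, 48.0),
        "regulon_offset_min": 12.0,
    },
    "cln1d_cln3d": {
        "period_min": 74.0,
        "onset_delay_min": 20.0,
        "phase_schedule": (24.0, 20.0, 30.0),
    },
    "cln2d_cln3d": {"oscillation_enabled": False},
}
#: extra onset delay added by osmotic stress; strains without a printed value
#: inherit the wild-type delay
_STRESS_DELAY = {"WT": 11.5, "cln1d": 16.9}


def make_strain_preset(name: str, stressed: bool = False) -> StrainPreset:
    """Return the generating preset for one strain/condition."""
    if name not in STRAIN_NAMES:
        raise ValueError(
            f"unknown strain {name!r}; valid labels: {', '.join(STRAIN_NAMES)}"
        )
    params = dict(_BASE)
    params.update(_STRAIN_OVERRIDES[name])
    onset = params["onset_delay_min"]
    if stressed:
        onset += _STRESS_DELAY.get(name, _STRESS_DELAY["WT"])
    halflife = math.inf if name == "cln2d_cln3d" else DEFAULT_ALPHA_HALFLIFE
    return StrainPreset(
        name=name,
        stressed=stressed,
        period_min=params["period_min"],
        onset_delay_min=onset,
        phase_schedule=params["phase_schedule"],
        regulon_offset_min=params["regulon_offset_min"],
        alpha_decay_halflife_min=halflife,
        oscillation_enabled=params["oscillation_enabled"],
        noise_cv=DEFAULT_NOISE_CV,
        synchrony_decay_per_min=DEFAULT_SYNCHRONY_DECAY,
    )


def default_time_grid() -> np.ndarray:
    """Experimental sampling grid: every 5 min to 60 min, then every 10 min
    to 150 min (22 points)."""
    return np.concatenate([np.arange(0, 61, 5), np.arange(70, 151, 10)]).astype(float)


def make_gene_panel(
    preset: StrainPreset,
    n_periodic: int = 600,
    n_mbf: int = 30,
    n_sbf: int = 30,
    n_alpha: int = 16,
    n_background: int = 400,
    seed: int = 0,
) -> list[GeneSpec]:
    """Build the default gene panel for one strain.

    The periodic genes fall into five clusters with peak times spread across
    the cycle (mirroring the five oscillating expression waves); MBF targets
    peak at the G1/S boundary and SBF targets exactly ``regulon_offset_min``
    later. When the preset has oscillations disabled, all periodic-class
    genes are emitted as background instead.
    """
    rng = np.random.default_rng(seed)
    specs: list[GeneSpec] = []
    period = preset.period_min
    osc = preset.oscillation_enabled

    def mean_level() -> float:
        return float(np.exp(rng.normal(np.log(400.0), 0.5)))

    # five coherent expression waves: tight peak-time and amplitude spread
    # within a wave, mirroring the narrow quantile bands of the real clusters
    centers = [period * (i + 0.5) / 5.0 for i in range(5)]
    for i in range(n_periodic):
        cluster = i % 5
        phi = (centers[cluster] + rng.normal(0.0, 1.0)) % period
        amp = rng.uniform(1.0, 1.2)
        if osc:
            specs.append(
                GeneSpec(f"OSC{i:04d}", f"oscillating-cluster-{cluster + 1}", phi, amp, mean_level())
            )
        else:
            specs.append(GeneSpec(f"OSC{i:04d}", "background", math.nan, 0.0, mean_level()))

    g1 = preset.phase_schedule[0]
    phi_mbf = g1 % period
    phi_sbf = (g1 + preset.regulon_offset_min) % period
    for i in range(n_mbf):
        if osc:
            specs.append(GeneSpec(f"MBF{i:03d}", "MBF-target", phi_mbf, rng.uniform(1.0, 1.5), mean_level()))
        else:
            specs.append(GeneSpec(f"MBF{i:03d}", "background", math.nan, 0.0, mean_level()))
    for i in range(n_sbf):
        if osc:
            specs.append(GeneSpec(f"SBF{i:03d}", "SBF-target", phi_sbf, rng.uniform(1.0, 1.5), mean_level()))
        else:
            specs.append(GeneSpec(f"SBF{i:03d}", "background", math.nan, 0.0, mean_level()))
    for i in range(n_alpha):
        induction = rng.uniform(2.5, 7.7)
        specs.append(GeneSpec(f"ALPHA{i:03d}", "alpha-response", math.nan, induction, mean_level()))
    for i in range(n_background):
        specs.append(GeneSpec(f"BG{i:04d}", "background", math.nan, 0.0, mean_level()))
    return specs


def expected_log2_signal(preset: StrainPreset, spec: GeneSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free log2-scale deviation of one periodic gene around its mean."""
    t = np.asarray(t, dtype=float)
    if spec.gene_class not in PERIODIC_CLASSES:
        return np.zeros_like(t)
    env = np.exp(-preset.synchrony_decay_per_min * t)
    phase = 2.0 * np.pi * (t - spec.phi_true - preset.onset_delay_min) / preset.period_min
    return spec.amplitude_true * env * np.cos(phase)


def expected_reads(preset: StrainPreset, spec: GeneSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free expected read counts of one gene on the time grid."""
    t = np.asarray(t, dtype=float)
    if spec.gene_class in PERIODIC_CLASSES:
        return spec.mean_level_true * 2.0 ** expected_log2_signal(preset, spec, t)
    if spec.gene_class == "alpha-response":
        if math.isinf(preset.alpha_decay_halflife_min):
            decay = np.ones_like(t)
        else:
            decay = 2.0 ** (-t / preset.alpha_decay_halflife_min)
        return spec.mean_level_true * (1.0 + spec.amplitude_true * decay)
    return np.full_like(t, spec.mean_level_true)


def simulate_expression(
    preset: StrainPreset,
    genes: list[GeneSpec],
    time_grid: np.ndarray | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Draw one raw-count matrix for a gene panel.

    Counts at each cell are Poisson around the expected reads, inflated by a
    unit-mean multiplicative lognormal factor with CV ``preset.noise_cv``.
    Deterministic for a fixed seed.
    """
    t = default_time_grid() if time_grid is None else np.asarray(time_grid, dtype=float)
    if len(t) and (t[0] != 0 or np.any(np.diff(t) <= 0)):
        raise ValueError("time_grid must be strictly increasing and start at 0")
    rng = np.random.default_rng(seed)
    n, T = len(genes), len(t)
    mu = np.empty((n, T))
    for i, spec in enumerate(genes):
        mu[i] = expected_reads(preset, spec, t)
    if preset.noise_cv > 0:
        sig = math.sqrt(math.log(1.0 + preset.noise_cv**2))
        factors = rng.lognormal(mean=-0.5 * sig**2, sigma=sig, size=(n, T))
        mu = mu * factors
    counts = rng.poisson(mu) if n else np.zeros((0, T), dtype=int)
    df = pd.DataFrame(counts, index=[g.gene_id for g in genes], columns=t.astype(int))
    return ExpressionMatrix(df, stage="raw_counts")


def simulate_reference_set(n_genes: int, seed: int = 0) -> ExpressionMatrix:
    """Strongly periodic reference trajectories for cutoff calibration.

    Wild-type preset with per-gene noise graded linearly from 0 to twice the
    default CV, so the reference spans clean to fairly noisy but genuinely
    periodic genes (standing in for a curated most-periodic gene list).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes < 5:
        warnings.warn(
            "reference sets below 5 genes cannot drive cutoff calibration",
            stacklevel=2,
        )
    preset = make_strain_preset("WT")
    rng = np.random.default_rng(seed)
    t = default_time_grid()
    cvs = np.linspace(0.0, 2.0 * DEFAULT_NOISE_CV, n_genes)
    rows = []
    ids = []
    for i in range(n_genes):
        spec = GeneSpec(
            f"REF{i:03d}",
            f"oscillating-cluster-{i % 5 + 1}",
            phi_true=float(rng.uniform(0.0, preset.period_min)),
            amplitude_true=float(rng.uniform(1.0, 1.5)),
            mean_level_true=float(np.exp(rng.normal(np.log(400.0), 0.3))),
        )
        mu = expected_reads(preset, spec, t)
        cv = cvs[i]
        if cv > 0:
            sig = math.sqrt(math.log(1.0 + cv**2))
            mu = mu * rng.lognormal(-0.5 * sig**2, sig, size=mu.shape)
        rows.append(rng.poisson(mu))
        ids.append(spec.gene_id)
    df = pd.DataFrame(np.asarray(rows), index=ids, columns=t.astype(int))
    return ExpressionMatrix(df, stage="raw_counts")


def simulate_tf_network(
    preset: StrainPreset,
    targets_per_tf: int = 50,
    seed: int = 0,
    time_grid: np.ndarray | None = None,
    n_background: int = 4000,
):
    """Emit a TF->target edge list plus the targets' count matrix.

    The four classification groups' targets peak at the preset's generating
    phase-transition times. Distractor TFs (fewer than three targets, or
    targets without periodic expression) are included so the oscillating-TF
    filter has something to discard. ``n_background`` untargeted flat genes
    pad the matrix: real transcriptomes are dominated by non-periodic mRNA
    (periodic transcripts carry roughly a tenth of the read mass), and
    without that ballast the per-column read totals would themselves
    oscillate and total-count normalization would distort every trajectory.

    Returns
    -------
    (TFNetwork, ExpressionMatrix)
    """
    from .tf_phase import TFNetwork  # local import to avoid a cycle

    if targets_per_tf < 3:
        raise ValueError("classification-set TFs need at least 3 targets")
    rng = np.random.default_rng(seed)
    boundaries = preset.phase_boundaries()
    # phi in GeneSpec is pre-onset; boundaries include onset, so subtract it
    osc = preset.oscillation_enabled
    specs: list[GeneSpec] = []
    edges: list[tuple[str, str, str]] = []

    def add_targets(tf: str, phi: float | None, n: int) -> None:
        for j in range(n):
            gid = f"{tf}_T{j:02d}"
            # the TF fixture has ~90 genes, so per-gene depth is higher than
            # in the transcriptome-wide panel to keep column totals above the
            # depth filter
            mean = float(np.exp(rng.normal(np.log(3000.0), 0.4)))
            if phi is None or not osc:
                specs.append(GeneSpec(gid, "background", math.nan, 0.0, mean))
            else:
                amp = float(rng.uniform(1.0, 1.5))
                specs.append(
                    GeneSpec(gid, "oscillating-cluster-1", phi % preset.period_min, amp, mean)
                )
            edges.append((tf, gid, "both"))

    for group_name, tfs in CLASSIFICATION_GROUPS:
        phi = boundaries[group_name] - preset.onset_delay_min
        for tf in tfs:
            add_targets(tf, phi, targets_per_tf)
    add_targets("DIST_SMALL", boundaries["G1/S"] - preset.onset_delay_min, 2)
    add_targets("DIST_FLAT", None, max(3, targets_per_tf // 2))
    for j in range(n_background):
        mean = float(np.exp(rng.normal(np.log(3000.0), 0.4)))
        specs.append(GeneSpec(f"BGTF{j:04d}", "background", math.nan, 0.0, mean))

    m = simulate_expression(preset, specs, time_grid=time_grid, seed=int(rng.integers(2**31)))
    net = TFNetwork(pd.DataFrame(edges, columns=["tf", "target", "evidence"]))
    return net, m


def simulate_bud_counts(
    preset: StrainPreset,
    times: np.ndarray | None = None,
    n_cells: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial cell/bud/large-daughter counts per time point.

    The generating budded fraction is a Gaussian bump over a baseline whose
    peak sits at 40 min for the wild type (shifted by any onset delay) and at
    60 min for the non-oscillating cln2d_cln3d strain.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if times is None:
        times = np.arange(0, 151, 10, dtype=float)
    times = np.asarray(times, dtype=float)
    peak = bud_peak_time(preset)
    rng = np.random.default_rng(seed)
    rows = []
    for t in times:
        p_bud = 0.10 + 0.60 * math.exp(-((t - peak) ** 2) / (2.0 * 15.0**2))
        p_large = 0.15 * p_bud
        p = np.array([1.0 - p_bud - p_large, p_bud, p_large])
        cells, buds, large = rng.multinomial(n_cells, p)
        rows.append((int(t), int(cells), int(buds), int(large)))
    return pd.DataFrame(rows, columns=["time_min", "cells", "buds", "large"])


def bud_peak_time(preset: StrainPreset) -> float:
    """Generating time of the maximal budded fraction."""
    if preset.name == "cln2d_cln3d":
        return 60.0
    return 40.0 + preset.onset_delay_min


def with_noise_cv(preset: StrainPreset, noise_cv: float) -> StrainPreset:
    """Convenience copy with a different multiplicative noise level."""
    return replace(preset, noise_cv=noise_cv)


def write_edge_list(net, path) -> None:
    """3-column TSV dialect: tf, target, evidence."""
    net.edges.to_csv(path, sep="\t", index=False)


def write_bud_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
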