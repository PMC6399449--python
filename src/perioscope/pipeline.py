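"""End-to-end orchestration: simulate -> preprocess -> periodicity ->
clustering/shift -> TF phases -> delays -> bud index, with a per-strain
summary report.

All thresholds live in :class:`RunConfig` with their standard defaults
(gene filter 10 reads, depth filter 7e4, 13 valid points, 20% calibration
FNR, 3 targets per TF, 20% lowess span, +/-10-point peak window, 40-min lag
bound) and round-trip through YAML. Runs are reproducible for a fixed seed;
every output table carries a header comment with the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering_shift, delay_metrics, periodicity, preprocess, synthetic, tf_phase

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    strains: list[str] = field(default_factory=lambda: ["WT"])
    stressed: bool = False
    seed: int = 0
    out_dir: str = "perioscope_out"
    # simulation scale
    n_periodic: int = 600
    n_mbf: int = 30
    n_sbf: int = 30
    n_alpha: int = 16
    n_background: int = 400
    n_reference: int = 200
    targets_per_tf: int = 50
    # thresholds (standard defaults)
    min_reads: float = 10.0
    min_total: float = 7e4
    min_points: int = 13
    fnr: float = 0.2
    min_targets: int = 3
    score_cutoff: float | None = None  # None: use the calibrated cutoff
    span: float = 0.2
    peak_window: int = 10
    max_lag: int = 40
    k_clusters: int = 12

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# perioscope {__version__} config={cfg.config_hash()} stage={stage}\n")
        df.to_csv(fh, sep="\t")


def _strain_seed(cfg: RunConfig, strain: str, salt: int) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{strain}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis for every configured strain.

    Returns the summary report as a dict (also written as TSVs under
    ``cfg.out_dir``): per strain the oscillating-gene count, median fitted
    period, phase durations, the MBF->SBF delay and, for non-wild-type
    strains, the lowess mean peak-time delay against the wild type.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # calibration from the reference periodic set
    # the reference is a curated gene subset, not a sequencing run: the
    # per-sample depth filter does not apply to its column totals
    ref = synthetic.simulate_reference_set(cfg.n_reference, seed=_strain_seed(cfg, "__ref__", 0))
    ref_fc = preprocess.preprocess_counts(ref, min_total=0.0, min_reads=cfg.min_reads)
    ref_fits = periodicity.fit_expression_matrix(ref_fc)
    cal = periodicity.calibrate_cutoffs(ref_fits, fnr=cfg.fnr)
    score_cutoff = cfg.score_cutoff if cfg.score_cutoff is not None else cal.score_cutoff
    logger.info("calibrated cutoffs: score %.3f bic_norm %.3f", cal.score_cutoff, cal.bicnorm_cutoff)

    report: dict = {"config_hash": cfg.config_hash(), "strains": {}}
    wt_fits_frame = None

    strains = list(cfg.strains)
    if "WT" not in strains:
        strains = ["WT"] + strains  # the shift analysis needs the reference strain
    for strain in strains:
        entry: dict = {}
        preset = synthetic.make_strain_preset(strain, stressed=cfg.stressed)
        panel = synthetic.make_gene_panel(
            preset,
            n_periodic=cfg.n_periodic,
            n_mbf=cfg.n_mbf,
            n_sbf=cfg.n_sbf,
            n_alpha=cfg.n_alpha,
            n_background=cfg.n_background,
            seed=_strain_seed(cfg, strain, 1),
        )
        counts = synthetic.simulate_expression(preset, panel, seed=_strain_seed(cfg, strain, 2))
        fc = preprocess.preprocess_counts(counts, min_total=cfg.min_total, min_reads=cfg.min_reads)
        fits = periodicity.fit_expression_matrix(fc)
        selected = periodicity.select_oscillating_genes(fits, cal, min_points=cfg.min_points)
        frame = periodicity.fits_to_frame(fits)
        _write_table(frame, out / f"{strain}_fits.tsv", cfg, "periodicity")
        entry["n_oscillating"] = len(selected)
        passing = frame[frame["pass"].astype(bool)]
        entry["median_lambda"] = float(passing["lambda"].median()) if len(passing) else None

        # clustering
        try:
            assign = clustering_shift.kmeans_trajectories(
                fc, k=cfg.k_clusters, seed=_strain_seed(cfg, strain, 3)
            )
            assign = clustering_shift.flag_oscillatory_clusters(assign, cal)
            cluster_df = pd.DataFrame(
                {
                    "cluster": assign.labels,
                    "oscillatory": assign.labels.map(
                        dict(zip(assign.centroids.index, assign.oscillatory_flags))
                    ),
                }
            )
            _write_table(cluster_df, out / f"{strain}_clusters.tsv", cfg, "clustering")
            entry["n_oscillatory_clusters"] = int(sum(assign.oscillatory_flags))
        except ValueError as exc:
            logger.warning("clustering skipped for %s: %s", strain, exc)

        # TF network phases
        net, tf_matrix = synthetic.simulate_tf_network(
            preset, targets_per_tf=cfg.targets_per_tf, seed=_strain_seed(cfg, strain, 4)
        )
        tf_fc = preprocess.preprocess_counts(tf_matrix, min_total=cfg.min_total, min_reads=cfg.min_reads)
        filtered = tf_phase.filter_oscillating_tfs(
            net, tf_fc, score_cutoff=score_cutoff, min_targets=cfg.min_targets
        )
        _write_table(tf_phase.network_table(filtered), out / f"{strain}_tf_network.tsv", cfg, "tf_phase")
        # classify on the filtered network: TFs that fail the oscillation
        # filter contribute no peaks (a strain without oscillating TFs ends
        # with an incomplete annotation)
        groups = [(name, list(tfs)) for name, tfs in synthetic.CLASSIFICATION_GROUPS]
        ann = tf_phase.classify_phases(
            groups, filtered, tf_fc, window=cfg.peak_window, strain=strain
        )
        _write_table(
            tf_phase.phase_table(ann).set_index("strain"),
            out / f"{strain}_phases.tsv",
            cfg,
            "tf_phase",
        )
        entry["phase_complete"] = ann.complete
        entry["phase_durations"] = ann.durations or None

        # regulon delays
        mbf = [g.gene_id for g in panel if g.gene_id.startswith("MBF")]
        sbf = [g.gene_id for g in panel if g.gene_id.startswith("SBF")]
        mbf = [g for g in mbf if g in fc.gene_ids]
        sbf = [g for g in sbf if g in fc.gene_ids]
        if preset.oscillation_enabled and mbf and sbf:
            est = delay_metrics.mbf_sbf_delay(fc, mbf, sbf, max_lag=cfg.max_lag)
            entry["mbf_sbf_delay"] = est.delay_min
        else:
            entry["mbf_sbf_delay"] = None

        # bud index
        buds = synthetic.simulate_bud_counts(preset, seed=_strain_seed(cfg, strain, 5))
        points, argmax_t = delay_metrics.bud_index(buds)
        entry["bud_index_peak_min"] = argmax_t

        # shift curve against the wild type
        if strain == "WT":
            wt_fits_frame = frame
        elif wt_fits_frame is not None and preset.oscillation_enabled:
            try:
                curve = clustering_shift.shift_curve_between(
                    wt_fits_frame, frame, span=cfg.span
                )
                entry["shift_mean_delay"] = curve.mean_delay
            except ValueError as exc:
                logger.warning("shift curve skipped for %s: %s", strain, exc)
        report["strains"][strain] = entry

    summary = pd.DataFrame(report["strains"]).T
    summary.index.name = "strain"
    _write_table(summary, out / "summary.tsv", cfg, "report")
    (out / "config.yaml").write_text(cfg.to_yaml())
    return report
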