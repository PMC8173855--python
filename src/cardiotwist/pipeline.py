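"""Orchestration: phantom -> tracking -> torsion/strain -> hemodynamics -> cohort stats.

A :class:`RunConfig` (YAML-loadable) fixes the species preset, seeds and
per-module parameters; :func:`run_subject` executes one subject's full
processing chain and returns a :class:`SubjectRecord`; :func:`run_cohort`
generates a metric-level cohort table and runs the statistics layer.  All
randomness derives from the config seed, so outputs are bit-identical
across re-runs of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contours import SA_LEVELS
from .errors import ConfigurationError
from .harp import rotation_from_tagged
from .hemo import HemoResult, analyze_waveform
from .phantom import (
    CohortConfig,
    PhantomSpec,
    PressureParams,
    deform,
    make_contours,
    reference_cohort_config,
    sample_cohort,
    simulate_cine_sequence,
    simulate_pressure,
    simulate_tagged_sequence,
)
from .stats import group_comparison_report, pca, univariate_regression, zscore
from .strain import average_repeats, peak_strain, strain_curves_from_tracked, track_contours
from .torsion import compute_torsion, lv_radius, peak_torsion_rate, resample_percent_systole

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SubjectRecord", "run_subject", "run_cohort", "power_harness", "config_hash"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    preset: str = "mouse"
    seed: int = 0
    subject_id: str = "subject_000"
    group: str = "sham"
    repeats: int = 3
    tag_noise_sd: float = 0.02
    cine_noise_sd: float = 0.02
    fade_per_frame: float = 0.98
    jitter_px: float = 0.3
    stats_route: str = "auto"
    torsion_peak_mode: str = "max_abs"
    phantom: Dict = field(default_factory=dict)
    pressure: Dict = field(default_factory=dict)
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.preset not in {"mouse", "human"}:
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")
        if self.stats_route not in {"auto", "ttest", "mannwhitney"}:
            raise ConfigurationError(f"unknown stats route {self.stats_route!r}")
        for noise in (self.tag_noise_sd, self.cine_noise_sd):
            if noise < 0:
                raise ConfigurationError("noise SD must be non-negative")
        # build domain objects now so invalid parameters fail before any computation
        self.build_spec()
        self.build_pressure_params()

    def build_spec(self) -> PhantomSpec:
        builder = PhantomSpec.mouse if self.preset == "mouse" else PhantomSpec.human
        return builder(**self.phantom)

    def build_pressure_params(self) -> PressureParams:
        defaults = (
            dict(pmax_true=35.0, pes_true=18.0, baseline=3.0, heart_rate_bpm=450.0,
                 sampling_hz=2000.0, stroke_volume_true_ml=0.04)
            if self.preset == "mouse"
            else dict(pmax_true=75.0, pes_true=30.0, baseline=5.0, heart_rate_bpm=100.0,
                      sampling_hz=1000.0, stroke_volume_true_ml=30.0)
        )
        defaults.update(self.pressure)
        return PressureParams(**defaults)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> Dict:
        return asdict(self)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SubjectRecord:
    """One subject's derived mechanics metrics with provenance."""

    subject_id: str
    species: str
    group: str
    peak_torsion_rate_deg_per_tau: float
    tau_at_peak: float
    lv_peak_radial_strain_pct: float
    lv_peak_circ_strain_pct: float
    lv_peak_long_strain_pct: float
    rv_peak_radial_strain_pct: float
    rv_peak_circ_strain_pct: float
    rv_peak_long_strain_pct: float
    lv_peak_displacement_mm: float
    rv_peak_displacement_mm: float
    hemo: Dict
    provenance: Dict

    def as_dict(self) -> Dict:
        return asdict(self)

    def metrics(self) -> Dict[str, float]:
        out = {
            k: v
            for k, v in self.as_dict().items()
            if k.endswith(("_pct", "_mm", "_per_tau"))
        }
        out["ees_mmhg_per_ml"] = self.hemo["ees_mmhg_per_ml"]
        return out


def _ground_truth_masks_and_centroids(
    spec: PhantomSpec, level: str
) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    masks, centroids = [], []
    for f in range(spec.n_frames):
        cs = make_contours(spec, f)
        masks.append(cs.lv_mask(level, spec.image_shape, spec.pixel_spacing_mm))
        centroids.append(cs.sa[(level, "lv_endo")].centroid)
    return masks, centroids


def torsion_from_phantom(
    spec: PhantomSpec,
    *,
    tag_noise_sd: float = 0.02,
    fade_per_frame: float = 0.98,
    seed: Optional[int] = None,
    peak_mode: str = "max_abs",
    step: float = 0.001,
):
    """Tagged rendering -> harmonic phase -> rotation -> torsion -> peak rate.

    Returns (TorsionRateResult, TorsionCurve, dict of RotationCurve).
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    curves = {}
    for level, child in zip(("base", "apex"), ss):
        seq = simulate_tagged_sequence(
            spec,
            level,
            fade_per_frame=fade_per_frame,
            noise_sd=tag_noise_sd,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        masks, centroids = _ground_truth_masks_and_centroids(spec, level)
        curves[level] = rotation_from_tagged(seq, masks, centroids)
    ed = make_contours(spec, 0)
    r_base = lv_radius(ed.sa[("base", "lv_endo")])
    r_apex = lv_radius(ed.sa[("apex", "lv_endo")])
    d_es = spec.base_apex_length_mm * deform(spec, spec.n_frames - 1).length_scale
    t_raw = compute_torsion(curves["base"], curves["apex"], r_apex, r_base, d_es)
    t = resample_percent_systole(t_raw, step=step)
    return peak_torsion_rate(t, mode=peak_mode), t, curves


def strain_from_phantom(
    spec: PhantomSpec,
    *,
    cine_noise_sd: float = 0.02,
    repeats: int = 3,
    jitter_px: float = 0.3,
    seed: Optional[int] = None,
):
    """Cine rendering -> contour tracking (repeated and averaged) -> strain peaks.

    Returns (StrainPeaks, StrainCurveSet of the first repeat).
    """
    ss = np.random.SeedSequence(seed).spawn(len(SA_LEVELS) + 1 + repeats)
    cines = {
        level: simulate_cine_sequence(
            spec, level, noise_sd=cine_noise_sd, seed=int(ss[i].generate_state(1)[0] % (2**31))
        )
        for i, level in enumerate(SA_LEVELS)
    }
    cine_la = simulate_cine_sequence(
        spec, "long_axis", noise_sd=cine_noise_sd,
        seed=int(ss[len(SA_LEVELS)].generate_state(1)[0] % (2**31)),
    )
    init = make_contours(spec, 0)
    all_peaks, first_curves = [], None
    for rep in range(repeats):
        rng = np.random.default_rng(ss[len(SA_LEVELS) + 1 + rep].generate_state(1)[0] % (2**31))
        jit = 0.0 if rep == 0 else jitter_px
        tracked_sa = {
            level: track_contours(cines[level], init, jitter_px=jit, rng=rng)
            for level in SA_LEVELS
        }
        # smaller template on the long axis: the wall is a thin elongated
        # band, and a wide template anchors on material deep in the wall,
        # which moves more than the endocardial edge under contraction
        tracked_la = track_contours(cine_la, init, jitter_px=jit, rng=rng, template_px=9)
        curves = strain_curves_from_tracked(tracked_sa, tracked_la)
        if first_curves is None:
            first_curves = curves
        all_peaks.append(peak_strain(curves))
    return average_repeats(all_peaks), first_curves


def run_subject(config: RunConfig) -> SubjectRecord:
    """One subject's full processing chain (idempotent at fixed seed)."""
    spec = config.build_spec()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]

    rate, torsion_curve, _ = torsion_from_phantom(
        spec,
        tag_noise_sd=config.tag_noise_sd,
        fade_per_frame=config.fade_per_frame,
        seed=seeds[0],
        peak_mode=config.torsion_peak_mode,
    )
    peaks, _ = strain_from_phantom(
        spec,
        cine_noise_sd=config.cine_noise_sd,
        repeats=config.repeats,
        jitter_px=config.jitter_px,
        seed=seeds[1],
    )
    params = config.build_pressure_params()
    waveform = simulate_pressure(params, seed=seeds[2])
    hemo: HemoResult = analyze_waveform(waveform, sv_ml=params.stroke_volume_true_ml)

    record = SubjectRecord(
        subject_id=config.subject_id,
        species=config.preset,
        group=config.group,
        peak_torsion_rate_deg_per_tau=rate.peak_rate_deg_per_tau,
        tau_at_peak=rate.tau_at_peak,
        lv_peak_radial_strain_pct=peaks.peaks["lv_radial"],
        lv_peak_circ_strain_pct=peaks.peaks["lv_circ"],
        lv_peak_long_strain_pct=peaks.peaks["lv_long"],
        rv_peak_radial_strain_pct=peaks.peaks.get("rv_radial", float("nan")),
        rv_peak_circ_strain_pct=peaks.peaks.get("rv_circ", float("nan")),
        rv_peak_long_strain_pct=peaks.peaks.get("rv_long", float("nan")),
        lv_peak_displacement_mm=peaks.peaks["lv_displacement"],
        rv_peak_displacement_mm=peaks.peaks.get("rv_displacement", float("nan")),
        hemo=hemo.as_dict(),
        provenance={
            "config_hash": config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "n_repeats": peaks.n_repeats,
        },
    )
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / f"{config.subject_id}.json").write_text(
            json.dumps(record.as_dict(), indent=2, sort_keys=True)
        )
    return record


def run_cohort(
    cohort: Optional[CohortConfig] = None,
    *,
    seed: int = 0,
    outdir: Optional[str] = None,
    route: str = "auto",
    k: int = 3,
    make_biplots: bool = True,
) -> Tuple[pd.DataFrame, Dict]:
    """Metric-level cohort run: sampling, comparisons, regression, PCA.

    Returns the cohort table and a JSON-serializable stats report.  When
    ``outdir`` is given, writes the table, report, PCA scores/loadings and
    biplot figures.
    """
    if cohort is None:
        cohort = reference_cohort_config(seed)
    table = sample_cohort(cohort)
    strain_cols = [c for c in table.columns if c.endswith("_pct")] + [
        "peak_torsion_rate_deg_per_tau"
    ]
    comparisons = group_comparison_report(table, columns=None, route=route)
    res = pca(table, k=k, columns=strain_cols)

    from sklearn.metrics import silhouette_score

    disease = table["group"].isin(["pah", "pab"]).to_numpy().astype(int)
    species = (table["species"] == "mouse").to_numpy().astype(int)
    pc1 = res.scores[:, :1]
    sil_disease = float(silhouette_score(pc1, disease))
    sil_species = float(silhouette_score(pc1, species))

    regressions = {}
    for grp in ("pah", "pab"):
        sub = table[table["group"] == grp]
        if "ees_mmhg_per_ml" in sub:
            reg = univariate_regression(sub["ees_mmhg_per_ml"], sub["peak_torsion_rate_deg_per_tau"])
            regressions[grp] = {"slope": reg.slope, "r": reg.r, "p_value": reg.p_value}

    report = {
        "seed": seed,
        "n_subjects": int(len(table)),
        "comparisons": comparisons.to_dict(orient="records"),
        "pca": {
            "explained_variance_ratio": res.explained_variance_ratio.tolist(),
            "metrics": list(res.metrics),
            "silhouette_pc1_by_disease": sil_disease,
            "silhouette_pc1_by_species": sil_species,
        },
        "torsion_ees_regression": regressions,
    }
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort.csv", index=False)
        (out / "stats_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        pd.DataFrame(res.scores, columns=[f"PC{i+1}" for i in range(res.k)]).assign(
            subject_id=table["subject_id"].values, group=table["group"].values
        ).to_csv(out / "pca_scores.csv", index=False)
        pd.DataFrame(res.loadings, index=res.metrics, columns=[f"PC{i+1}" for i in range(res.k)]).to_csv(
            out / "pca_loadings.csv"
        )
        if make_biplots:
            _write_biplots(table, res, out)
    return table, report


def _write_biplots(table: pd.DataFrame, res, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"control": "tab:blue", "pah": "tab:red", "sham": "tab:cyan", "pab": "tab:orange"}
    markers = {"human": "o", "mouse": "^"}
    for pcx, pcy in ((0, 1), (0, 2)):
        if max(pcx, pcy) >= res.k:
            continue
        fig, ax = plt.subplots(figsize=(6, 5))
        for grp, sub in table.groupby("group"):
            idx = table.index.get_indexer(sub.index)
            sp = sub["species"].iloc[0]
            ax.scatter(
                res.scores[idx, pcx], res.scores[idx, pcy],
                c=colors.get(grp, "gray"), marker=markers.get(sp, "o"), label=grp, alpha=0.8,
            )
        scale = np.abs(res.scores[:, [pcx, pcy]]).max() * 0.9
        for m, vec in zip(res.metrics, res.loadings[:, [pcx, pcy]]):
            ax.annotate(m, xy=(0, 0), xytext=vec * scale, fontsize=6,
                        arrowprops=dict(arrowstyle="<-", lw=0.5, color="gray"))
        ax.set_xlabel(f"PC{pcx + 1}")
        ax.set_ylabel(f"PC{pcy + 1}")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / f"biplot_pc{pcx + 1}_pc{pcy + 1}.png", dpi=120)
        plt.close(fig)


def power_harness(
    cohort_factory=reference_cohort_config,
    metrics: Sequence[str] = ("peak_torsion_rate_deg_per_tau",),
    pairs: Sequence[Tuple[str, str]] = (("sham", "pab"), ("control", "pah")),
    n_seeds: int = 1000,
    alpha: float = 0.05,
    base_seed: int = 0,
    route: str = "auto",
) -> pd.DataFrame:
    """Rejection fraction per comparison over seeded cohort re-draws."""
    counts = {(g1, g2, m): 0 for g1, g2 in pairs for m in metrics}
    from .stats import compare_groups

    for s in range(n_seeds):
        table = sample_cohort(cohort_factory(base_seed + s))
        for g1, g2 in pairs:
            a = table[table["group"] == g1]
            b = table[table["group"] == g2]
            for m in metrics:
                if compare_groups(a[m], b[m], route=route).p_value < alpha:
                    counts[(g1, g2, m)] += 1
    rows = [
        {"group_a": g1, "group_b": g2, "metric": m, "rejection_fraction": c / n_seeds}
        for (g1, g2, m), c in counts.items()
    ]
    return pd.DataFrame(rows)
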