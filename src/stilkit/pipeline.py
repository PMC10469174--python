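"""End-to-end orchestration of the synthetic reader study.

One call runs the whole workflow: generate slides and cells → score every
slide with the simulated automated reader and the simulated pathologist
panel → initial concordance statistics → standalone evaluation of the
automated reader on the concordant subset → triage → automated-assisted
revision → post-revision concordance → neoadjuvant-response analysis, and
packages everything into a machine-readable report bundle whose every number
is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import io as stio
from .errors import InvalidConfigError
from .response import StratumConfig, response_analysis
from .scoring import ScoringConfig, score_slide
from .synthetic import (
    CohortConfig,
    IntensityConfig,
    RaterProfile,
    ReaderErrorProfile,
    detection_metrics,
    generate_cells,
    generate_cohort,
    generate_tissue_map,
    simulate_dl_reader,
    simulate_rater,
    true_stil,
)
from .triage import TriageConfig, revision_accounting, simulate_revision, triage

logger = logging.getLogger("stilkit")

AUTOMATED_READER = "DL"


def default_rater_profiles() -> dict[str, RaterProfile]:
    """Four pathologist profiles with distinct biases, mirroring a panel
    whose members systematically read low (A) or high (B, C) of consensus."""
    return {
        "A": RaterProfile("A", additive_bias=-6.0, noise_sd=0.35),
        "B": RaterProfile("B", additive_bias=5.0, noise_sd=0.40),
        "C": RaterProfile("C", additive_bias=3.0, noise_sd=0.45),
        "D": RaterProfile("D", additive_bias=0.0, noise_sd=0.30),
    }


@dataclass
class StudyConfig:
    """Synthetic study geometry and generative settings.

    Slides are square rasters of ``slide_um`` μm per side at ``mpp`` μm/px.
    Per-slide lymphoid density is lognormal around ``density_median``
    (cells/mm² of stroma, log-sd ``density_log_sd``) so that the cohort
    spans the low/intermediate/high sTIL strata.
    """

    n_slides: int = 50
    slide_um: float = 1200.0
    mpp: float = 2.0
    stroma_fraction: float = 0.40
    cancer_fraction: float = 0.35
    density_median: float = 5000.0
    density_log_sd: float = 0.8
    heterogeneity: float = 1.0
    field_correlation_length: float = 200.0
    tumor_density: float = 4000.0
    fraction_scored_by_b: float = 256.0 / 402.0  # remainder goes to rater D


@dataclass
class RunConfig:
    study: StudyConfig = field(default_factory=StudyConfig)
    raters: dict[str, RaterProfile] = field(default_factory=default_rater_profiles)
    reader: ReaderErrorProfile = field(default_factory=ReaderErrorProfile)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)
    stratum: StratumConfig = field(default_factory=StratumConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    revision_noise_sd: float = 0.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw: dict = {}
        if "study" in d:
            kw["study"] = StudyConfig(**d["study"])
        if "raters" in d:
            kw["raters"] = {
                r["rater_id"]: RaterProfile(**r) for r in d["raters"]
            } if isinstance(d["raters"], list) else {
                k: RaterProfile(rater_id=k, **v) for k, v in d["raters"].items()
            }
        for key, typ in (
            ("reader", ReaderErrorProfile),
            ("scoring", ScoringConfig),
            ("triage", TriageConfig),
            ("stratum", StratumConfig),
            ("cohort", CohortConfig),
        ):
            if key in d:
                sub = dict(d[key])
                if key == "cohort" and "grade_cutpoints" in sub:
                    sub["grade_cutpoints"] = tuple(sub["grade_cutpoints"])
                kw[key] = typ(**sub)
        for key in ("revision_noise_sd", "seed"):
            if key in d:
                kw[key] = d[key]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["raters"] = {k: asdict(v) for k, v in self.raters.items()}
        return d


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


@dataclass
class ReportBundle:
    config: dict
    slides: pd.DataFrame  # per-slide truth, automated score, realized IoU
    panel_initial: pd.DataFrame
    panel_revised: pd.DataFrame
    automated: pd.Series
    cohort: pd.DataFrame
    results: dict

    def to_json(self) -> str:
        payload = {"config": _jsonable(self.config), "results": _jsonable(self.results)}
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json())
        self.slides.to_csv(outdir / "slides.csv", index=False)
        stio.write_score_panel(self.panel_initial, outdir / "panel_initial.csv")
        stio.write_score_panel(self.panel_revised, outdir / "panel_revised.csv")
        self.automated.rename("DL").to_frame().rename_axis("slide_id").to_csv(outdir / "automated.csv")
        stio.write_cohort(self.cohort, outdir / "cohort.csv")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(_jsonable(self.config), fh, sort_keys=True)


def _ccc_matrix_dict(panel: pd.DataFrame) -> dict:
    mat = conc.pairwise_ccc(panel)
    out = {}
    for a in mat.index:
        for b in mat.columns:
            if a < b:
                cell = mat.loc[a, b]
                out[f"{a}~{b}"] = None if cell is None else asdict(cell)
    return out


def _panel_mean(panel: pd.DataFrame) -> pd.Series:
    return panel.mean(axis=1)


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


def run_full_study(cfg: RunConfig | None = None, seed: int | None = None) -> ReportBundle:
    """Run the complete synthetic reader study and return the report bundle.

    Deterministic for a fixed (config, seed): all randomness is drawn from
    a seed sequence derived from ``seed`` (defaults to ``cfg.seed``).
    """
    cfg = cfg or RunConfig()
    seed = cfg.seed if seed is None else seed
    study = cfg.study
    if study.n_slides < 3:
        raise InvalidConfigError("need at least 3 slides")
    root = np.random.SeedSequence(seed)
    ss_slides, ss_panel, ss_revision, ss_cohort = root.spawn(4)
    slide_seeds = ss_slides.spawn(study.n_slides)

    rater_ids = list(cfg.raters)
    if len(rater_ids) < 2:
        raise InvalidConfigError("need at least 2 raters")
    # Reader design: first two raters review every slide; the third slot
    # alternates between the remaining raters by cohort position.
    n_b = int(round(study.fraction_scored_by_b * study.n_slides))

    logger.info("generating %d slides", study.n_slides)
    slide_rows = []
    panel_rows = []
    auto_scores = {}
    panel_rngs = np.random.default_rng(ss_panel)
    for i, ss in enumerate(slide_seeds):
        rng = np.random.default_rng(ss)
        slide_id = f"slide_{i:04d}"
        density = study.density_median * float(np.exp(rng.normal(0.0, study.density_log_sd)))
        tmap = generate_tissue_map(
            study.slide_um,
            study.slide_um,
            mpp=study.mpp,
            stroma_fraction=study.stroma_fraction,
            cancer_fraction=study.cancer_fraction,
            seed=rng,
            slide_id=slide_id,
            correlation_length_um=study.field_correlation_length,
        )
        icfg = IntensityConfig(
            base_density=density,
            heterogeneity=study.heterogeneity,
            field_correlation_length=study.field_correlation_length,
            tumor_density=study.tumor_density,
        )
        cells = generate_cells(tmap, icfg, seed=rng)
        truth = true_stil(tmap, cells)
        reader = simulate_dl_reader(tmap, cells, cfg.reader, seed=rng, scoring_config=cfg.scoring)
        metrics = detection_metrics(
            cells, reader.detected_cells, truth_map=tmap, degraded_map=reader.degraded_map
        )
        auto_scores[slide_id] = reader.score
        scores: dict[str, float] = {}
        if len(rater_ids) <= 3:
            scoring_raters = rater_ids
        else:
            # first two raters review every slide; third slot split between the rest
            third = rater_ids[2] if i < n_b else rater_ids[3]
            scoring_raters = rater_ids[:2] + [third]
        for rid in scoring_raters:
            scores[rid] = simulate_rater(tmap, cells, cfg.raters[rid], seed=panel_rngs)
        panel_rows.append(scores)
        slide_rows.append(
            {
                "slide_id": slide_id,
                "true_stil": truth.true_stil,
                "stroma_area_um2": truth.stroma_area_um2,
                "lymphoid_in_stroma": truth.lymphoid_in_stroma,
                "automated_score": reader.score,
                "realized_stroma_iou": reader.realized_stroma_iou,
                "lymphoid_f1": metrics["f1"]["lymphoid"].f1,
                "tumor_f1": metrics["f1"]["tumor"].f1,
            }
        )
    slides = pd.DataFrame(slide_rows)
    panel = pd.DataFrame(panel_rows, index=slides["slide_id"]).reindex(columns=rater_ids)
    automated = pd.Series(auto_scores, name=AUTOMATED_READER)

    logger.info("initial concordance")
    ccc_before = _ccc_matrix_dict(panel)
    cov_before = conc.cov_per_case(panel)
    mean_before = _panel_mean(panel)

    tri = triage(panel, automated, cfg.triage)
    concordant_ids = tri.concordant.index[tri.concordant]
    standalone = None
    if len(concordant_ids) >= 3:
        standalone = asdict(
            conc.lins_ccc(mean_before[concordant_ids].to_numpy(), automated[concordant_ids].to_numpy())
        )

    logger.info("revision (%d flagged entries)", int(tri.revisit.to_numpy().sum()))
    outcome = simulate_revision(
        panel, automated, cfg.raters, tri, seed=np.random.default_rng(ss_revision), noise_sd=cfg.revision_noise_sd
    )
    accounting = revision_accounting(tri, outcome, panel, cfg.triage)
    ccc_after = _ccc_matrix_dict(outcome.revised)
    cov_after = conc.cov_per_case(outcome.revised)
    mean_after = _panel_mean(outcome.revised)

    ba_before, ba_after = {}, {}
    for a in rater_ids:
        for b in rater_ids:
            if a < b:
                shared = panel[[a, b]].dropna()
                if len(shared) >= 3:
                    ba_before[f"{a}~{b}"] = asdict(conc.bland_altman(shared[a], shared[b]))
                    rev = outcome.revised.loc[shared.index]
                    ba_after[f"{a}~{b}"] = asdict(conc.bland_altman(rev[a], rev[b]))

    logger.info("response cohort and regression")
    n_her2 = int(round(study.n_slides * cfg.cohort.n_her2 / cfg.cohort.n_total))
    ccfg = dataclasses.replace(
        cfg.cohort, n_total=study.n_slides, n_her2=n_her2, n_tnbc=study.n_slides - n_her2
    )
    cohort = generate_cohort(
        ccfg, slides["true_stil"].to_numpy(), seed=np.random.default_rng(ss_cohort), slide_ids=list(slides["slide_id"])
    )
    cohort = cohort.merge(
        pd.DataFrame(
            {
                "slide_id": slides["slide_id"],
                "stil_initial": mean_before.to_numpy(),
                "stil_revised": mean_after.to_numpy(),
                "stil_automated": automated.reindex(slides["slide_id"]).to_numpy(),
            }
        ),
        on="slide_id",
    )
    response = {}
    for mode in ("stil_initial", "stil_revised", "stil_automated"):
        response[mode] = {}
        for subset in ("all", "HER2_positive", "TNBC"):
            try:
                response[mode][subset] = response_analysis(cohort, mode, subset, cfg.stratum)
            except Exception as e:  # degenerate subsets stay reported, not fatal
                response[mode][subset] = {"error": str(e)}

    results = {
        "n_slides": study.n_slides,
        "seed": seed,
        "slides": {
            "mean_true_stil": float(slides["true_stil"].mean()),
            "mean_realized_stroma_iou": float(slides["realized_stroma_iou"].mean()),
            "mean_lymphoid_f1": float(slides["lymphoid_f1"].mean()),
        },
        "concordance_before": {
            "pairwise_ccc": ccc_before,
            "cov_mean": cov_before.mean,
            "cov_sd": cov_before.sd,
        },
        "standalone_ccc_concordant": standalone,
        "triage": {
            "n_concordant": tri.n_concordant,
            "n_discordant": tri.n_discordant,
            "discordant_fraction_pct": 100.0 * tri.discordant_fraction,
        },
        "accounting": {
            "per_rater": _jsonable(accounting.per_rater.reset_index().to_dict(orient="records")),
            "unique_revisited": accounting.unique_revisited,
            "unique_revisited_pct": accounting.unique_revisited_pct,
            "multiplicity_strata": accounting.multiplicity_strata,
            "discordant_before": accounting.discordant_before,
            "discordant_after": accounting.discordant_after,
            "discordant_before_pct": accounting.discordant_before_pct,
            "discordant_after_pct": accounting.discordant_after_pct,
            "mcnemar_b": accounting.mcnemar_b,
            "mcnemar_c": accounting.mcnemar_c,
            "mcnemar_p": accounting.mcnemar_p,
        },
        "concordance_after": {
            "pairwise_ccc": ccc_after,
            "cov_mean": cov_after.mean,
            "cov_sd": cov_after.sd,
        },
        "bland_altman": {"before": ba_before, "after": ba_after},
        "response": response,
    }
    bundle = ReportBundle(
        config=cfg.to_dict(),
        slides=slides,
        panel_initial=panel,
        panel_revised=outcome.revised,
        automated=automated,
        cohort=cohort,
        results=results,
    )
    return bundle
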