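"""End-to-end pipeline: cohort -> fit -> ROC -> cross-validation -> volcano.

A single :class:`RunConfig` (typically loaded from a YAML file) drives the
whole analysis.  The pipeline either reads a cohort CSV or simulates one,
fits the requested classifier, writes the ROC table, runs the Monte-Carlo
cross-validation and the volcano screens, and collects everything into one
JSON report.  Every configuration field is serialised into the report, so a
report fully documents its own provenance; two runs with the same config
produce identical reports.  Log lines carry the stage name, the seed and
the elapsed time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__
from .classifier import optimize_F, optimize_GF
from .data_model import CohortTable, read_cohort, write_cohort
from .diffstats import welch_volcano
from .errors import MetaboStratError
from .synthetic import generate_cohort, spec_from_mapping, spec_to_mapping
from .validation import SplitConfig, cross_validate, roc_curve_F, roc_region_GF

logger = logging.getLogger("metabostrat")

DEFAULT_VOLCANO_PAIRS = [
    ("BC", "H"),
    ("LC", "H"),
    ("ODminus", "H"),
    ("ODplus", "H"),
]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``input`` points at a cohort CSV; when None, a synthetic cohort is
    generated from ``synthetic`` (partial overrides of the default spec).
    Defaults mirror the study constants: 0.75 training probability, 100,000
    realisations, obesity prevalence 0.2.
    """

    input: str | None = None
    synthetic: dict = dataclasses.field(default_factory=dict)
    classifier: str = "GF"
    p_o: float = 0.2
    train_probability: float = 0.75
    n_realisations: int = 100_000
    seed: int = 0
    outdir: str = "metabostrat-out"
    volcano_pairs: list = dataclasses.field(
        default_factory=lambda: [list(p) for p in DEFAULT_VOLCANO_PAIRS]
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MetaboStratError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str, seed, t0: float) -> None:
    logger.info("stage=%s seed=%s elapsed=%.2fs", name, seed, time.perf_counter() - t0)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to
    ``<outdir>/report.json``).  Raises on the first failing stage; artifacts
    of completed stages are retained."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": cfg.as_dict(), "stages": {}}

    # -- cohort -------------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.input is not None:
        path = Path(cfg.input)
        if not path.exists():
            raise MetaboStratError(f"input cohort file not found: {path}")
        cohort = read_cohort(path)
        source = str(path)
    else:
        spec = spec_from_mapping(dict(cfg.synthetic, seed=cfg.synthetic.get("seed", cfg.seed)))
        cohort = generate_cohort(spec)
        source = "synthetic"
        write_cohort(cohort, outdir / "cohort.csv")
        report["stages"]["simulate"] = {"spec": spec_to_mapping(spec)}
    report["stages"]["cohort"] = {
        "source": source,
        "n": len(cohort),
        "class_counts": cohort.class_counts(),
        "subtype_counts": cohort.subtype_counts(),
    }
    _stage("cohort", cfg.seed, t0)

    # -- fit ----------------------------------------------------------------
    t0 = time.perf_counter()
    fit = optimize_GF(cohort) if cfg.classifier == "GF" else optimize_F(cohort)
    fit_payload = {
        "classifier": cfg.classifier,
        "F_0": fit.thresholds.f_t,
        "G_0": fit.thresholds.g_t,
        "relative_mutual_information": fit.rmi,
        "n_train": fit.n_train,
        "class_counts": fit.class_counts,
    }
    (outdir / "thresholds.json").write_text(json.dumps(fit_payload, indent=2))
    report["stages"]["fit"] = fit_payload
    _stage("fit", cfg.seed, t0)

    # -- ROC ----------------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.classifier == "GF":
        roc = roc_region_GF(cohort, p_o=cfg.p_o)
    else:
        include_obesity = cfg.p_o > 0
        roc = roc_curve_F(cohort, include_obesity=include_obesity, p_o=cfg.p_o)
    roc.to_csv(outdir / "roc.csv", index=False)
    report["stages"]["roc"] = {"n_points": len(roc), "path": "roc.csv"}
    _stage("roc", cfg.seed, t0)

    # -- cross-validation ---------------------------------------------------
    t0 = time.perf_counter()
    cv = cross_validate(
        cohort,
        cfg.classifier,
        SplitConfig(
            train_probability=cfg.train_probability,
            n_realisations=cfg.n_realisations,
            seed=cfg.seed,
            p_o=cfg.p_o,
        ),
    )
    cv_payload = {
        "tpr": cv.tpr.as_dict(),
        "skipped": cv.skipped,
        "n_realisations": cfg.n_realisations,
    }
    if cfg.p_o > 0 or cfg.classifier == "GF":
        cv_payload["fpr"] = cv.fpr.as_dict()
    else:
        # p_o = 0 with the F-classifier: the plain healthy-only FPR, no
        # obesity-weighted quantity exists in this configuration
        cv_payload["fpr_unweighted"] = cv.fpr.as_dict()
    (outdir / "evaluate.json").write_text(json.dumps(cv_payload, indent=2))
    report["stages"]["evaluate"] = cv_payload
    _stage("evaluate", cfg.seed, t0)

    # -- volcano ------------------------------------------------------------
    t0 = time.perf_counter()
    volcano_summary = {}
    for case, control in cfg.volcano_pairs:
        table = welch_volcano(cohort, case, control)
        name = f"volcano_{case}_vs_{control}.csv"
        table.to_csv(outdir / name, index=False)
        volcano_summary[f"{case}_vs_{control}"] = {
            "path": name,
            "n_significant_1e3": int((table["p_value"] < 1e-3).sum()),
            "n_significant_1e6": int((table["p_value"] < 1e-6).sum()),
        }
    report["stages"]["volcano"] = volcano_summary
    _stage("volcano", cfg.seed, t0)

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
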