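"""End-to-end workflow: simulate/load -> pretreat -> split -> train ->
validate -> applicability domain -> report bundle."""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import domain as ad
from . import gfa, pretreatment, splitting, synthetic, validation
from .io import Dataset, read_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Either ``input_csv`` (with ``id_column``/``activity_column``) or a
    synthetic-data block is used as the source. Every stochastic stage
    receives a sub-seed derived deterministically from ``seed``.
    """

    seed: int = 0
    out_dir: str = "qsarpipe_run"
    # source
    input_csv: Optional[str] = None
    id_column: str = "ID"
    activity_column: str = "pKi"
    missing_policy: str = "drop_column"
    simulate: Optional[dict] = None
    # pretreatment
    variance_tol: float = 1e-6
    r_threshold: float = 0.95
    normalize_variant: str = "paper"
    # splitting
    n_train: int = 36
    # GFA
    population_size: int = 100
    generations: int = 500
    min_terms: int = 2
    max_terms: int = 6
    smoothing_d: float = 0.5
    mutation_rate: float = 0.1
    crossover_rate: float = 0.9
    elitism: int = 2
    stagnation_patience: int = 50
    # validation
    y_randomization_iterations: int = 10
    r2_test_variant: str = "standard"
    hstar_variant: str = "eq9"
    write_plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed (stable across processes)."""
        tag = zlib.crc32(stage.encode("utf-8"))
        return int(np.random.default_rng([self.seed, tag]).integers(2**31))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and write per-stage artifacts plus a
    combined report. Returns the report bundle (a plain dict).

    Identical config + seed produce identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    bundle: dict = {"config": asdict(config)}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 4)
            logger.info("stage %s done in %.3fs", name, timings[name])
            return result
        return wrap

    # -- source ---------------------------------------------------------------
    if config.input_csv:
        dataset = stage("load")(lambda: read_dataset(
            config.input_csv, config.id_column, config.activity_column,
            config.missing_policy))
        truth = None
    else:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", config.stage_seed("simulate"))
        spec = synthetic.SyntheticSpec(**sim_kwargs)
        dataset, truth = stage("simulate")(lambda: synthetic.generate_dataset(spec))
        write_dataset(dataset, out / "dataset.csv")
        _dump(truth.to_dict(), out / "ground_truth.json")

    # -- pretreatment ---------------------------------------------------------
    dataset_v, log_v = stage("variance_filter")(
        lambda: pretreatment.remove_low_variance(dataset, config.variance_tol))
    dataset_c, log_c = stage("correlation_filter")(
        lambda: pretreatment.correlation_filter(dataset_v, config.r_threshold))
    _dump({"variance": log_v.to_dict(), "correlation": log_c.to_dict()},
          out / "pretreatment_log.json")

    # -- split (Kennard-Stone on min-max scaled full data, distances only) ----
    def _split():
        span_params = pretreatment.fit_normalizer(dataset_c, variant="minmax")
        scaled = pretreatment.apply_normalizer(dataset_c, span_params)
        return splitting.kennard_stone_split(scaled, config.n_train)

    split = stage("split")(_split)
    _dump(split.to_dict(), out / "split.json")
    train_raw = dataset_c.subset(split.train_ids)
    test_raw = dataset_c.subset(split.test_ids) if split.test_ids else None

    # -- normalization fitted on the training partition only ------------------
    def _normalize():
        params = pretreatment.fit_normalizer(train_raw, variant=config.normalize_variant)
        tr = pretreatment.apply_normalizer(train_raw, params)
        te = pretreatment.apply_normalizer(test_raw, params) if test_raw else None
        return tr, te

    train, test = stage("normalize")(_normalize)

    stats = {
        "train": splitting.describe_activity(train.y).to_dict(),
        "test": splitting.describe_activity(test.y).to_dict() if test else None,
    }

    # -- GFA training ---------------------------------------------------------
    gfa_config = gfa.GFAConfig(
        population_size=config.population_size,
        generations=config.generations,
        min_terms=config.min_terms,
        max_terms=config.max_terms,
        d=config.smoothing_d,
        mutation_rate=config.mutation_rate,
        crossover_rate=config.crossover_rate,
        elitism=config.elitism,
        seed=config.stage_seed("gfa"),
        stagnation_patience=config.stagnation_patience,
    )
    ranked = stage("train")(lambda: gfa.gfa_search(train, gfa_config))
    best_model, best_score = ranked[0]
    _dump(
        [
            {"model": m.to_dict(), "lof": s.lof}
            for m, s in ranked[: min(10, len(ranked))]
        ],
        out / "models.json",
    )
    _dump(best_model.to_dict(), out / "model.json")

    # -- validation -----------------------------------------------------------
    report = stage("validate")(lambda: validation.validate_model(
        best_model, train, test, r2_test_variant=config.r2_test_variant))
    yrand = stage("y_randomization")(lambda: validation.y_randomization(
        train.X[best_model.descriptor_names], train.y.to_numpy(),
        n_iterations=config.y_randomization_iterations,
        seed=config.stage_seed("y_randomization")))
    checklist = validation.acceptance_checklist(report, yrand)
    _dump(report.to_dict(), out / "validation.json")
    _dump(yrand.to_dict(), out / "y_randomization.json")
    _dump(checklist, out / "checklist.json")

    # -- applicability domain -------------------------------------------------
    ad_result = stage("domain")(lambda: ad.williams_table(
        best_model, train, test, hstar_variant=config.hstar_variant))
    ad_result.to_frame().to_csv(out / "applicability_domain.csv")
    _dump(ad_result.to_dict(), out / "applicability_domain.json")
    if config.write_plot:
        ad.plot_williams(ad_result, out / "williams.png")

    bundle.update({
        "n_compounds": dataset.n_compounds,
        "n_descriptors_raw": dataset.n_descriptors,
        "n_descriptors_pretreated": dataset_c.n_descriptors,
        "split": split.to_dict(),
        "descriptive_stats": stats,
        "model": best_model.to_dict(),
        "lof": best_score.lof,
        "validation": report.to_dict(),
        "y_randomization": yrand.to_dict(),
        "checklist": checklist,
        "applicability_domain": ad_result.to_dict(),
        "ground_truth": truth.to_dict() if truth else None,
    })
    # timings go to a side log so the report bundle is byte-reproducible
    _dump({"timings": timings}, out / "run_log.json")
    _dump(bundle, out / "report.json")
    (out / "report.md").write_text(render_report(bundle))
    return bundle


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

_STAT_ROWS = (
    ("n", "Dataset number", "{:d}"),
    ("standard_error", "Standard error", "{:.3f}"),
    ("median", "Median", "{:.3f}"),
    ("standard_deviation", "Standard deviation", "{:.3f}"),
    ("sample_variance", "Sample variance", "{:.3f}"),
    ("kurtosis", "Kurtosis", "{:.3f}"),
    ("skewness", "Skewness", "{:.3f}"),
    ("range", "Range", "{:.3f}"),
    ("minimum", "Minimum", "{:.3f}"),
    ("maximum", "Maximum", "{:.3f}"),
    ("mean", "Mean", "{:.3f}"),
)


def _fmt(value, spec="{:.4f}") -> str:
    if value is None:
        return "-"
    return spec.format(value)


def render_report(bundle: dict) -> str:
    """Deterministic markdown rendering of a pipeline bundle.

    All numbers are formatted at fixed precision; no arithmetic happens
    here — every figure is computed by a pipeline stage.
    """
    lines = ["# QSAR pipeline report", ""]
    lines += [
        f"- compounds: {bundle['n_compounds']}",
        f"- descriptors: {bundle['n_descriptors_raw']} raw, "
        f"{bundle['n_descriptors_pretreated']} after pretreatment",
        f"- split: {len(bundle['split']['train_ids'])} train / "
        f"{len(bundle['split']['test_ids'])} test",
        "",
    ]

    lines += ["## Partition descriptive statistics", ""]
    lines += ["| Statistic | Training set | Test set |", "|---|---|---|"]
    stats = bundle["descriptive_stats"]
    for key, label, spec in _STAT_ROWS:
        tr = stats["train"].get(key)
        te = stats["test"].get(key) if stats["test"] else None
        lines.append(f"| {label} | {_fmt(tr, spec)} | {_fmt(te, spec)} |")
    lines.append("")

    model = bundle["model"]
    terms = " + ".join(
        f"{coef:+.4f}*{name}" for name, coef in model["coefficients"].items()
    )
    lines += ["## Selected model", "",
              f"    activity = {terms} {model['intercept']:+.4f}", ""]

    val = bundle["validation"]
    lines += [
        "## Fit and validation statistics", "",
        f"- R^2 (train): {_fmt(val['r2'])}",
        f"- adjusted R^2: {_fmt(val['r2_adjusted'])}",
        f"- SEE: {_fmt(val['see'])}",
        f"- F: {_fmt(val['f_statistic'], '{:.2f}')}",
        f"- Q^2 (LOO): {_fmt(val['q2_loo'])}",
        f"- R^2 (test): {_fmt(val['r2_test'])}",
        "",
    ]

    lines += ["## Descriptor contributions", "",
              "| Descriptor | b* | % contribution |", "|---|---|---|"]
    for name, (bstar, pct) in val["contributions"].items():
        lines.append(f"| {name} | {bstar:.3f} | {pct:.1f} |")
    lines.append("")

    lines += ["## Collinearity and inference", "",
              "| Descriptor | VIF | t | p |", "|---|---|---|---|"]
    for name, v in val["vif"].items():
        rec = val["coefficients"][name]
        lines.append(f"| {name} | {v:.4f} | {rec['t']:.4f} | {rec['p']:.3g} |")
    lines.append("")

    yr = bundle["y_randomization"]
    lines += ["## Y-randomization", "",
              "| Model | R | R^2 | Q^2 |", "|---|---|---|---|"]
    orig = yr["original"]
    lines.append(f"| Original | {orig[0]:.4f} | {orig[1]:.4f} | {orig[2]:.4f} |")
    for k, (r, r2, q2) in enumerate(yr["iterations"], start=1):
        lines.append(f"| Random {k} | {r:.4f} | {r2:.4f} | {q2:.4f} |")
    lines += [
        "",
        f"- average R: {yr['average_r']:.4f}",
        f"- average R^2: {yr['average_r2']:.4f}",
        f"- average Q^2: {yr['average_q2']:.4f}",
        f"- cRp^2: {yr['crp2']:.4f}",
        "",
    ]

    lines += ["## Acceptance checklist", "",
              "| Criterion | Value | Verdict |", "|---|---|---|"]
    for key, rec in bundle["checklist"].items():
        if key == "overall":
            continue
        lines.append(
            f"| {rec['description']} | {_fmt(rec['value'])} | {rec['verdict']} |"
        )
    lines.append(f"| **overall** | | {bundle['checklist']['overall']['verdict']} |")
    lines.append("")

    adres = bundle["applicability_domain"]
    n_out = sum(
        1 for rec in adres["compounds"].values() if rec["flag"] != "in_domain"
    )
    lines += [
        "## Applicability domain", "",
        f"- warning leverage h*: {adres['warning_leverage']:.4f}",
        f"- outliers: {n_out} of {len(adres['compounds'])}",
        "",
    ]
    return "\n".join(lines)
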