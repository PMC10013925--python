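"""End-to-end orchestration: scan -> mine -> validate -> classify -> pi0 -> rescue.

`run_scan` walks a directory of processed tables and produces exactly one
record per file (ok / dropped-by-prefilter / import-failure / no-p-values /
failed-validation / unclassifiable), aggregating the ok records into a
corpus summary. `run_rescue` applies low-count filtering to every
filterable table. `run_simulate` writes synthetic corpora to disk. All
randomness (the one-set-per-file choice, simulator seeds) derives from the
run seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import filtering, histogram, mining, pi0 as pi0mod
from .filtering import DEFAULT_THRESHOLDS, NotFilterableError
from .histogram import CLASSES
from .synthetic import (
    DIALECTS, CountSimConfig, FixtureSpec, MixtureConfig,
    generate_malformed_set, generate_pvalue_set, simulate_count_experiment,
    write_fixture, MALFORMED_KINDS,
)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a corpus scan; echoed verbatim into every report."""

    input_dir: str
    output_dir: str | None = None
    bins: int = histogram.DEFAULT_BINS
    alpha: float = histogram.DEFAULT_ALPHA
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    lambda_grid: tuple[float, ...] = tuple(float(x) for x in pi0mod.DEFAULT_LAMBDA_GRID)
    seed: int = 0
    all_sets: bool = False
    rescue: bool = True

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class CorpusSummary:
    """Descriptive summary of one scan over a directory of tables."""

    config: RunConfig
    records: list[dict[str, Any]]
    class_counts: dict[str, int]
    class_proportions: dict[str, float]
    pi0_histogram: dict[str, Any]
    transition: dict[str, Any] | None

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "n_files": len(self.records),
            "class_counts": self.class_counts,
            "class_proportions": self.class_proportions,
            "pi0_histogram": self.pi0_histogram,
            "transition": self.transition,
            "records": self.records,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _file_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), zlib.crc32(name.encode())])


def _analyze_one_set(values, config: RunConfig) -> dict[str, Any]:
    verdict = mining.validate_pvalue_set(values)
    out: dict[str, Any] = {"validation": verdict.status}
    if not verdict.ok:
        out["status"] = "failed_validation"
        return out
    report = histogram.classify_set(values, bins=config.bins, alpha=config.alpha)
    out["class"] = report.klass
    out["m"] = report.m
    out["qc_threshold"] = report.qc_threshold
    out["flagged_bins"] = list(report.flagged_bins)
    if report.klass == histogram.UNCLASSIFIABLE:
        out["status"] = "unclassifiable"
        return out
    out["status"] = "ok"
    if report.klass in filtering.PI0_ELIGIBLE:
        finite = values[np.isfinite(values)]
        out["pi0_lfdr"] = pi0mod.pi0_lfdr(finite).value
        if finite.size >= 100:
            out["pi0_smoother"] = pi0mod.pi0_storey_smoother(
                finite, lambda_grid=np.asarray(config.lambda_grid)).value
    return out


def run_scan(config: RunConfig) -> CorpusSummary:
    """Scan every file in ``config.input_dir``; aggregate ok records."""
    root = Path(config.input_dir)
    if not root.is_dir():
        raise NotADirectoryError(config.input_dir)
    records: list[dict[str, Any]] = []
    rescue_results: list[filtering.RescueResult] = []
    pi0_values: list[float] = []
    class_counts = {k: 0 for k in CLASSES}

    for path in sorted(root.iterdir()):
        if not path.is_file() or path.name.endswith(".manifest.json"):
            continue
        rec: dict[str, Any] = {"file": path.name}
        records.append(rec)
        if not mining.filename_passes_prefilter(path.name):
            rec["status"] = "dropped_by_prefilter"
            continue
        table, failure = mining.try_read_table(path)
        if table is None:
            rec["status"] = "import_failure"
            rec["detail"] = failure
            continue
        pcols = mining.find_pvalue_columns(table)
        if not pcols:
            rec["status"] = "no_pvalue_columns"
            continue
        rec["tool"] = mining.infer_de_tool(table).tool
        if config.all_sets:
            chosen = list(pcols)
        else:
            rng = _file_rng(config.seed, path.name)
            chosen = [pcols[int(rng.integers(len(pcols)))]]
        sets_out = []
        for col in chosen:
            values = table.numeric(col)
            one = {"column": col} | _analyze_one_set(values, config)
            sets_out.append(one)
            if one["status"] == "ok":
                class_counts[one["class"]] += 1
                for key in ("pi0_lfdr", "pi0_smoother"):
                    if key in one:
                        pi0_values.append(one[key])
                if config.rescue:
                    try:
                        rr = filtering.rescue_set(
                            table, bins=config.bins, alpha=config.alpha,
                            thresholds=config.thresholds, pvalue_column=col)
                        one["rescue"] = rr.to_dict()
                        rescue_results.append(rr)
                    except NotFilterableError:
                        one["rescue"] = "not_filterable"
        rec["sets"] = sets_out
        rec["status"] = ("ok" if any(s["status"] == "ok" for s in sets_out)
                         else sets_out[0]["status"])

    total = sum(class_counts.values())
    proportions = {k: (v / total if total else 0.0) for k, v in class_counts.items()}
    edges = np.linspace(0.0, 1.0, 21)
    hist, _ = np.histogram(pi0_values, bins=edges)
    transition = None
    if rescue_results:
        tm = filtering.transition_summary(rescue_results)
        transition = {
            "matrix": {b: {a: int(tm.matrix.loc[b, a]) for a in CLASSES}
                       for b in CLASSES},
            "before_proportions": {k: float(v) for k, v in tm.before_proportions.items()},
            "after_proportions": {k: float(v) for k, v in tm.after_proportions.items()},
        }
    return CorpusSummary(
        config=config,
        records=records,
        class_counts=class_counts,
        class_proportions=proportions,
        pi0_histogram={"edges": edges.tolist(), "counts": hist.tolist()},
        transition=transition,
    )


def run_rescue(config: RunConfig) -> tuple[list[dict[str, Any]], dict[str, Any]]:
    """Apply the filtering rescue to every filterable table in a directory."""
    root = Path(config.input_dir)
    if not root.is_dir():
        raise NotADirectoryError(config.input_dir)
    per_set: list[dict[str, Any]] = []
    results: list[filtering.RescueResult] = []
    for path in sorted(root.iterdir()):
        if not path.is_file() or path.name.endswith(".manifest.json"):
            continue
        if not mining.filename_passes_prefilter(path.name):
            continue
        table, _failure = mining.try_read_table(path)
        if table is None or not mining.find_pvalue_columns(table):
            continue
        try:
            rr = filtering.rescue_set(table, bins=config.bins, alpha=config.alpha,
                                      thresholds=config.thresholds)
        except NotFilterableError:
            per_set.append({"file": path.name, "status": "not_filterable"})
            continue
        per_set.append({"file": path.name, "status": "ok"} | rr.to_dict())
        results.append(rr)
    if results:
        tm = filtering.transition_summary(results)
        summary = {
            "matrix": {b: {a: int(tm.matrix.loc[b, a]) for a in CLASSES}
                       for b in CLASSES},
            "before_proportions": {k: float(v) for k, v in tm.before_proportions.items()},
            "after_proportions": {k: float(v) for k, v in tm.after_proportions.items()},
            "n_filterable": tm.total,
        }
    else:
        summary = {"matrix": None, "n_filterable": 0}
    return per_set, summary


def run_simulate(kind: str, params: dict[str, Any], out_dir) -> dict[str, Any]:
    """Write a synthetic corpus (mixture / malformed / counts / fixtures).

    Returns the manifest (also written to ``out_dir/manifest.json``) with
    the ground truth of every file written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(params.get("seed", 0))
    entries: list[dict[str, Any]] = []

    if kind == "mixture":
        cfg = MixtureConfig(
            n_features=int(params.get("n_features", 20_000)),
            pi0=float(params.get("pi0", 0.8)),
            alt_model=str(params.get("alt_model", "ztest")),
            delta=float(params.get("delta", 2.0)),
            seed=seed)
        ps = generate_pvalue_set(cfg)
        path = out / "mixture.tsv"
        _write_pset(ps, path)
        entries.append({"file": path.name, "true_pi0": cfg.pi0,
                        "n_features": cfg.n_features, "seed": seed})
    elif kind == "malformed":
        kinds = params.get("kinds", MALFORMED_KINDS)
        for i, mk in enumerate(kinds):
            ps = generate_malformed_set(mk, int(params.get("n_features", 20_000)),
                                        seed=seed + i)
            path = out / f"malformed_{mk}.tsv"
            _write_pset(ps, path)
            entries.append({"file": path.name, "kind": mk,
                            "nominal_class": ps.meta["nominal_class"],
                            "seed": seed + i})
    elif kind == "counts":
        cfg = CountSimConfig(
            n_features=int(params.get("n_features", 20_000)),
            n_per_group=int(params.get("n_per_group", 3)),
            frac_de=float(params.get("frac_de", 0.1)),
            frac_low_count=float(params.get("frac_low_count", 0.0)),
            log2_fold_change=float(params.get("log2_fold_change", 1.0)),
            seed=seed)
        table = simulate_count_experiment(cfg)
        path = out / "counts.tsv"
        table.df.to_csv(path, sep="\t", index=False)
        entries.append({"file": path.name, "config": cfg.__dict__ | {}, "seed": seed})
    elif kind == "fixtures":
        dialects = params.get("dialects", DIALECTS)
        table = simulate_count_experiment(CountSimConfig(
            n_features=int(params.get("n_features", 2000)), seed=seed))
        for dialect in dialects:
            spec = FixtureSpec(dialect=dialect)
            path = out / f"fixture_{dialect}.tsv"
            manifest = write_fixture(spec, table, path)
            entries.append(manifest)
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")

    manifest = {"kind": kind, "seed": seed, "entries": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    return manifest


def _write_pset(ps, path: Path) -> None:
    import pandas as pd

    df = pd.DataFrame({"feature": np.arange(ps.values.size), "pvalue": ps.values})
    if ps.is_alternative is not None:
        df["true_alternative"] = ps.is_alternative.astype(int)
    df.to_csv(path, sep="\t", index=False)
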