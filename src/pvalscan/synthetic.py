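"""Synthetic p-value sets, count experiments, and table fixtures.

Everything downstream (classification, pi0 estimation, filtering rescue)
is exercised against data generated here with known ground truth, so no
external corpus is needed. Three generators:

* mixtures of Uniform(0,1) nulls with stochastically small alternatives
  (z-test transform or Beta), the canonical model behind anti-conservative
  histograms;
* malformed sets (conservative spikes at one, bimodal ends, mid-range
  humps, interior atoms) of the kinds produced by discrete tests on low
  counts or by mangled exports;
* two-group negative-binomial count experiments with per-feature tests
  computed internally, whose low-count features yield honest discrete
  p-value artifacts;

plus a fixture writer that renders a table in a chosen column-naming
dialect alongside a ground-truth role manifest.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .mining import ProcessedTable, assign_column_roles
from .pvalues import PValueSet

MALFORMED_KINDS = ("conservative", "bimodal", "hump", "spiky")
#: Histogram class each malformed kind is constructed to receive.
NOMINAL_CLASS = {
    "conservative": "conservative",
    "bimodal": "bimodal",
    "hump": "other",
    "spiky": "other",
}

DIALECTS = ("cuffdiff", "deseq", "deseq2", "edger", "limma", "unknown")


@dataclass(frozen=True)
class MixtureConfig:
    """Uniform-null / small-alternative mixture for one p-value set.

    ``alt_model="ztest"`` draws z ~ Normal(delta, 1) and sets p = 1 - Phi(z)
    (one-sided), so per-test power at level a is Phi(delta - z_{1-a});
    ``alt_model="beta"`` draws p ~ Beta(a, b) with a < 1 <= b. The number of
    alternatives is exactly round((1 - pi0) * n_features).
    """

    n_features: int = 20_000
    pi0: float = 0.8
    alt_model: str = "ztest"
    delta: float = 2.0
    beta_a: float = 0.2
    beta_b: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must lie in [0, 1]")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.alt_model not in ("ztest", "beta"):
            raise ValueError(f"unknown alt_model {self.alt_model!r}")
        if self.alt_model == "beta" and not (0 < self.beta_a < 1 <= self.beta_b):
            raise ValueError("beta alternative requires a < 1 <= b")


def generate_pvalue_set(config: MixtureConfig) -> PValueSet:
    """Draw one mixture p-value set with ground-truth null/alternative labels."""
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    n_alt = int(round((1.0 - config.pi0) * n))
    values = np.empty(n, dtype=float)
    labels = np.zeros(n, dtype=bool)
    labels[:n_alt] = True
    if n_alt:
        if config.alt_model == "ztest":
            z = rng.normal(config.delta, 1.0, size=n_alt)
            values[:n_alt] = stats.norm.sf(z)
        else:
            values[:n_alt] = rng.beta(config.beta_a, config.beta_b, size=n_alt)
    values[n_alt:] = rng.random(n - n_alt)
    return PValueSet(
        values=values, source_column="simulated_mixture", is_alternative=labels,
        meta={"config": config.__dict__ | {}, "seed": config.seed},
    )


# Component tables for malformed shapes: (weight, sampler-kind, params).
# Weights chosen so that at 20,000 features the intended bins clear the
# peak threshold (~567) by several standard deviations while the uniform
# background (~360-430 per bin) stays well below it, and so that the
# bimodal shape keeps its left end at least as heavy as its right (a
# heavier right end would trip the right-skew validity screen).
_MALFORMED_COMPONENTS: dict[str, list[tuple[float, str, tuple]]] = {
    "conservative": [
        (0.72, "uniform", (0.0, 1.0)),
        (0.18, "uniform", (0.925, 1.0)),
        (0.10, "point", (1.0,)),
    ],
    "bimodal": [
        (0.72, "uniform", (0.0, 1.0)),
        (0.16, "uniform", (0.0, 0.05)),
        (0.10, "uniform", (0.95, 1.0)),
        (0.02, "point", (1.0,)),
    ],
    "hump": [
        (0.80, "uniform", (0.0, 1.0)),
        (0.20, "truncnorm", (0.5, 0.08)),
    ],
    "spiky": [
        (0.85, "uniform", (0.0, 1.0)),
        (0.05, "point", (0.1573,)),
        (0.05, "point", (0.3173,)),
        (0.05, "point", (0.6547,)),
    ],
}


def generate_malformed_set(kind: str, n_features: int = 20_000, seed: int = 0) -> PValueSet:
    """Draw a p-value set with a deliberately malformed histogram shape.

    ``conservative`` concentrates mass near one (including an atom at
    exactly 1.0, as discrete tests produce); ``bimodal`` loads both
    outermost bins; ``hump`` adds a unimodal bump centred at 0.5; ``spiky``
    plants atoms at interior values. ``NOMINAL_CLASS[kind]`` is the class
    the default classifier assigns with high probability at 20,000 features.
    """
    if kind not in MALFORMED_KINDS:
        raise ValueError(f"unknown malformed kind {kind!r}")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(seed)
    comps = _MALFORMED_COMPONENTS[kind]
    weights = np.array([w for w, _, _ in comps])
    which = rng.choice(len(comps), size=n_features, p=weights / weights.sum())
    values = np.empty(n_features, dtype=float)
    for idx, (_, sampler, params) in enumerate(comps):
        mask = which == idx
        k = int(mask.sum())
        if k == 0:
            continue
        if sampler == "uniform":
            lo, hi = params
            values[mask] = rng.uniform(lo, hi, size=k)
        elif sampler == "point":
            values[mask] = params[0]
        elif sampler == "truncnorm":
            mu, sd = params
            a, b = (0.0 - mu) / sd, (1.0 - mu) / sd
            values[mask] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                                               size=k, random_state=rng)
    return PValueSet(
        values=values, source_column=f"simulated_{kind}",
        meta={"kind": kind, "seed": seed, "nominal_class": NOMINAL_CLASS[kind]},
    )


@dataclass(frozen=True)
class CountSimConfig:
    """Two-group negative-binomial count experiment.

    Feature means are drawn on the log2 scale: low-count features (a
    ``frac_low_count`` fraction) from Uniform(-2, 2.3), giving group mean
    counts below 5 at unit depth, the rest from a 9-log2-unit window
    centred at ``mean_log2_expression``. DE features (a ``frac_de``
    fraction) have their group-2 mean scaled by 2**(+-log2_fold_change),
    sign random per feature. Counts are NB with the given dispersion;
    library depths vary about 1 so size-factor estimation is non-trivial.
    """

    n_features: int = 20_000
    n_per_group: int = 3
    mean_log2_expression: float = 7.5
    dispersion: float = 0.05
    frac_de: float = 0.1
    log2_fold_change: float = 1.0
    frac_low_count: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for name in ("frac_de", "frac_low_count"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB with var = mu + dispersion * mu^2: size r = 1/dispersion.
    r = 1.0 / dispersion
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    return out


def _size_factors(counts: np.ndarray) -> tuple[np.ndarray, str]:
    """Median-of-ratios size factors; total-count fallback below 100 usable rows."""
    all_pos = np.all(counts > 0, axis=1)
    if int(all_pos.sum()) >= 100:
        logc = np.log(counts[all_pos])
        ref = logc.mean(axis=1)
        sf = np.exp(np.median(logc - ref[:, None], axis=0))
        return sf, "median_of_ratios"
    totals = counts.sum(axis=0).astype(float)
    sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return sf, "total_count"


def _welch_pvalues(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values with explicit degenerate handling.

    Both groups zero-variance with equal means -> p = 1 (no evidence);
    zero-variance with unequal means -> p = 0 (the infinite-t artifact a
    naive test on constant low counts actually produces).
    """
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant rows are expected at low counts; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = log_a.var(axis=1, ddof=1)
    var_b = log_b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    equal = degenerate & (log_a.mean(axis=1) == log_b.mean(axis=1))
    p[degenerate & ~equal] = 0.0
    p[equal] = 1.0
    p[~np.isfinite(p)] = 1.0
    return p


def _poisson_pair_pvalues(c1: np.ndarray, c2: np.ndarray,
                          s1: float, s2: float) -> np.ndarray:
    """Exact conditional (binomial) test for a single count pair per feature.

    Conditional on the total, c1 ~ Binomial(c1 + c2, s1 / (s1 + s2)) under
    the null; two-sided by the doubling rule p = min(1, 2 min(lower, upper)).
    Zero totals give p = 1. Heavily discrete at low counts, with atoms at 1.
    """
    n_tot = c1 + c2
    pi = s1 / (s1 + s2)
    lower = stats.binom.cdf(c1, n_tot, pi)
    upper = stats.binom.sf(c1 - 1, n_tot, pi)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p[n_tot == 0] = 1.0
    return p


def simulate_count_experiment(config: CountSimConfig) -> ProcessedTable:
    """Simulate counts, test each feature, and return a processed table.

    The table carries ``baseMean`` (mean of size-factor-normalized counts),
    ``pvalue`` (Welch t on log2(count / size factor + 0.5) for two or more
    replicates; exact conditional Poisson pair test for one), and the
    ground-truth ``true_de`` label. Raw counts and size factors are kept in
    ``meta`` so baseMean can be recomputed exactly.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_features, config.n_per_group

    n_low = int(round(config.frac_low_count * n))
    low = np.zeros(n, dtype=bool)
    low[rng.permutation(n)[:n_low]] = True
    log2_mean = np.where(
        low,
        rng.uniform(-2.0, 2.3, size=n),
        rng.uniform(config.mean_log2_expression - 4.5,
                    config.mean_log2_expression + 4.5, size=n),
    )
    mu = 2.0 ** log2_mean

    n_de = int(round(config.frac_de * n))
    de = np.zeros(n, dtype=bool)
    de[rng.permutation(n)[:n_de]] = True
    sign = rng.choice([-1.0, 1.0], size=n)
    mu2 = mu * np.where(de, 2.0 ** (sign * config.log2_fold_change), 1.0)

    depth = 2.0 ** rng.uniform(-0.5, 0.5, size=2 * k)  # per-library depth
    mean_mat = np.concatenate(
        [mu[:, None] * depth[None, :k], mu2[:, None] * depth[None, k:]], axis=1)
    counts = _nb_draw(rng, mean_mat, config.dispersion)

    sf, sf_method = _size_factors(counts)
    norm = counts / sf[None, :]
    base_mean = norm.mean(axis=1)

    if k >= 2:
        logn = np.log2(norm + 0.5)
        pvals = _welch_pvalues(logn[:, :k], logn[:, k:])
        test = "welch_t_log2"
    else:
        pvals = _poisson_pair_pvalues(
            counts[:, 0].astype(float), counts[:, 1].astype(float), sf[0], sf[1])
        test = "poisson_pair_exact"

    df = pd.DataFrame({
        "baseMean": base_mean,
        "pvalue": pvals,
        "true_de": de.astype(int),
    })
    return ProcessedTable(
        df=df, source_path="simulated_counts",
        meta={
            "config": config.__dict__ | {}, "seed": config.seed,
            "counts": counts, "size_factors": sf, "size_factor_method": sf_method,
            "test": test, "low_count": low,
        },
    )


@dataclass(frozen=True)
class FixtureSpec:
    """A processed-table fixture in a given column-naming dialect."""

    dialect: str = "deseq2"
    delimiter: str = "\t"
    gzip: bool = False
    include_adjusted: bool = True
    n_pvalue_columns: int = 1

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.delimiter not in ("\t", ",", ";"):
            raise ValueError("delimiter must be tab, comma or semicolon")
        if self.n_pvalue_columns < 1:
            raise ValueError("need at least one p-value column")


# Per-dialect layout: ordered (column name, role, metric or None, source).
# source: "pvalue" | "adjusted" | "expression" | "stat" | "id"
_DIALECT_LAYOUTS: dict[str, list[tuple[str, str, str | None, str]]] = {
    "deseq2": [
        ("baseMean", "expression", "basemean", "expression"),
        ("log2FoldChange", "other", None, "stat"),
        ("lfcSE", "other", None, "stat"),
        ("stat", "other", None, "stat"),
        ("pvalue", "pvalue", None, "pvalue"),
        ("padj", "adjusted", None, "adjusted"),
    ],
    "deseq": [
        ("baseMean", "expression", "basemean", "expression"),
        ("log2FoldChange", "other", None, "stat"),
        ("pval", "pvalue", None, "pvalue"),
        ("padj", "adjusted", None, "adjusted"),
    ],
    "edger": [
        ("logFC", "other", None, "stat"),
        ("logCPM", "expression", "logcpm", "expression"),
        ("LR", "other", None, "stat"),
        ("PValue", "pvalue", None, "pvalue"),
        ("FDR", "adjusted", None, "adjusted"),
    ],
    "limma": [
        ("logFC", "other", None, "stat"),
        ("AveExpr", "expression", "aveexpr", "expression"),
        ("t", "other", None, "stat"),
        ("P.Value", "pvalue", None, "pvalue"),
        ("adj.P.Val", "adjusted", None, "adjusted"),
        ("B", "other", None, "stat"),
    ],
    "cuffdiff": [
        ("gene_id", "other", None, "id"),
        ("value_1", "expression", "value", "expression"),
        ("value_2", "expression", "value", "expression"),
        ("log2(fold_change)", "other", None, "stat"),
        ("p_value", "pvalue", None, "pvalue"),
        ("q_value", "adjusted", None, "adjusted"),
    ],
    "unknown": [
        ("feature", "other", None, "id"),
        ("score", "other", None, "stat"),
        ("p-val", "pvalue", None, "pvalue"),
    ],
}

#: Ground-truth tool label per dialect (what the column heuristics should say).
DIALECT_TOOL = {
    "deseq2": "deseq2", "deseq": "deseq", "edger": "edger",
    "limma": "limma", "cuffdiff": "cuffdiff", "unknown": "unknown",
}


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from scipy.stats import false_discovery_control
    return false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")


def write_fixture(spec: FixtureSpec, table: ProcessedTable, path) -> dict[str, Any]:
    """Render a processed table in the requested dialect and write a manifest.

    The input table must carry a ``pvalue``-role column and (except for the
    'unknown' dialect) an ``expression``-role column; these are mapped onto
    the dialect's column names. Statistic columns are deterministic
    transforms of the p-values, the adjusted column is Benjamini-Hochberg.
    Returns the ground-truth manifest (also written to ``<path>.manifest.json``)
    listing every column's true role for mining precision/recall tests.
    """
    path = Path(path)
    pcols = table.columns_with_role("pvalue")
    ecols = table.columns_with_role("expression")
    if not pcols:
        raise ValueError("fixture source table has no p-value column")
    p = np.clip(np.nan_to_num(table.numeric(pcols[0]), nan=1.0), 1e-300, 1.0)
    expr = table.numeric(ecols[0]) if ecols else np.ones_like(p)
    z = stats.norm.isf(p / 2.0)  # deterministic stand-in statistic

    layout = list(_DIALECT_LAYOUTS[spec.dialect])
    if not spec.include_adjusted:
        layout = [c for c in layout if c[3] != "adjusted"]
    for extra in range(2, spec.n_pvalue_columns + 1):
        base = next(c for c in _DIALECT_LAYOUTS[spec.dialect] if c[3] == "pvalue")
        layout.append((f"{base[0]}_{extra}", "pvalue", None, "pvalue"))

    n = len(p)
    cols: dict[str, Any] = {}
    for name, role, metric, source in layout:
        if source == "pvalue":
            cols[name] = p
        elif source == "adjusted":
            cols[name] = _bh_adjust(p)
        elif source == "expression":
            cols[name] = expr
        elif source == "id":
            cols[name] = [f"FEAT{i:06d}" for i in range(n)]
        else:  # stat
            cols[name] = np.round(z * (0.5 if name.lower().startswith("l") else 1.0), 6)
    df = pd.DataFrame(cols)

    text = df.to_csv(sep=spec.delimiter, index=False)
    try:
        if spec.gzip:
            with gzip.open(path, "wt", encoding="utf-8") as fh:
                fh.write(text)
        else:
            path.write_text(text, encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write fixture to {path}: {exc}") from exc

    manifest = {
        "path": str(path),
        "dialect": spec.dialect,
        "delimiter": {"\t": "tab", ",": "comma", ";": "semicolon"}[spec.delimiter],
        "gzip": spec.gzip,
        "tool": DIALECT_TOOL[spec.dialect],
        "n_rows": n,
        "columns": [
            {"name": name, "role": role, "metric": metric}
            for name, role, metric, _ in layout
        ],
    }
    manifest_path = path.with_name(path.name + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest


def _roles_match_manifest(manifest: dict[str, Any]) -> bool:
    """Check the miner reproduces the manifest's roles (used in tests/CLI)."""
    inferred = assign_column_roles([c["name"] for c in manifest["columns"]])
    return all(
        inferred[c["name"]].role == c["role"]
        and (inferred[c["name"]].metric or None) == (c["metric"] or None)
        for c in manifest["columns"]
    )
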