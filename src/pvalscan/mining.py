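"""Mining p-value and expression columns from processed HT-seq tables.

Processed differential-expression tables deposited in public repositories
come in many dialects (cuffdiff, DESeq/DESeq2, edgeR, limma, home-grown).
This module parses such tables, assigns every column a role (pvalue /
adjusted / expression / other) from its name alone, screens p-value sets
for disqualifying defects, infers the DE analysis tool, and applies the
balanced-design sample-size rule.

All name and text matching is done on lower-cased strings.
"""

from __future__ import annotations

import csv
import gzip
import io
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .pvalues import PValueSet

# --- column-name regexes (applied to lower-cased names) -------------------

#: Unadjusted p-value columns: "p", up to 4 non-letters, then "val".
PVALUE_RE = re.compile(r"p[^a-zA-Z]{0,4}val")
#: Adjusted / derived significance columns.
ADJUSTED_RE = re.compile(r"adj|fdr|corr|thresh")
#: q-value style columns, treated as adjusted even without an "adj" marker.
QVALUE_RE = re.compile(r"q[^a-zA-Z]{0,4}val")
#: Expression-level metrics, longest match wins.
EXPRESSION_PATTERNS = ("basemean", "aveexpr", "logcpm", "value", "fpkm", "rpkm")

#: Filename patterns where p-values are not expected (drop before reading).
DROP_FILENAME_RE = re.compile(
    r"series_matrix\.txt\.gz$|filelist\.txt$|readme|\.bam(\.tdf|$)|\.bai(\.gz|$)"
    r"|\.sam(\.gz|$)|\.csfasta|\.fa(sta)?(\.gz|\.bz2|\.txt\.gz|$)|\.f(a|n)a(\.gz|$)"
    r"|\.wig|\.big[Ww]ig$|\.bw(\.|$)|\.bed([Gg]raph)?(\.tdf|\.gz|\.bz2|\.txt\.gz|$)"
    r"|(broad_)?lincs|\.tdf$|\.hic$|\.rds(\.gz|$)|\.tar\.gz$|\.mtx(\.gz$|$)"
    r"|dge\.txt\.gz$|umis?\.txt\.gz$"
)
ACCEPTED_EXTENSIONS = {"tab", "xlsx", "diff", "tsv", "xls", "csv", "txt", "rtf", "tar"}

#: Free-text DE tool extraction (applied to lower-cased text).
TOOL_TEXT_RE = re.compile(
    r"deseq2?|de(g|x)seq|rockhopper|cuff(diff|links)|edger|clc(bio)?? genomics"
    r"|igeak|bayseq|samseq|noiseq|ebseq|limma|voom|sleuth|partek"
    r"|(nrsa|nascent rna seq)|median ratio norm|rmats|ballgown|biojupie|seurat|exdega"
)

VALIDATION_STATUSES = ("ok", "out_of_range", "all_nan", "truncated", "right_skewed")


@dataclass(frozen=True)
class ColumnRole:
    role: str  # pvalue | adjusted | expression | other
    metric: str | None = None  # expression metric when role == "expression"


@dataclass(frozen=True)
class ValidationVerdict:
    status: str
    detail: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass(frozen=True)
class DEToolLabel:
    tool: str
    evidence: str  # "column_heuristic" | "text_regex"


@dataclass(frozen=True)
class SampleSizeRecord:
    n_samples: int
    n_pvalue_sets: int
    per_group_n: int | None


class TableImportError(RuntimeError):
    """Raised when a file cannot be parsed into a table."""


@dataclass
class ProcessedTable:
    """A parsed table with deterministic column-role assignments."""

    df: pd.DataFrame
    source_path: str = ""
    roles: dict[str, ColumnRole] = field(default_factory=dict)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.roles:
            self.roles = assign_column_roles(self.df.columns)

    @property
    def n_rows(self) -> int:
        return int(len(self.df))

    def numeric(self, column: str) -> np.ndarray:
        """Column values coerced to float; non-numeric cells become NaN."""
        return pd.to_numeric(self.df[column], errors="coerce").to_numpy(dtype=float)

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r.role == role]

    def pvalue_set(self, column: str) -> PValueSet:
        values = self.numeric(column)
        return PValueSet(values=values, source_column=column,
                         meta={"source_path": self.source_path})


def assign_column_roles(columns) -> dict[str, ColumnRole]:
    """Assign every column exactly one role from its (lower-cased) name.

    Precedence: adjusted (adj/fdr/corr/thresh markers or q-value style)
    beats pvalue, which beats expression, which beats other. The expression
    metric is the longest matching pattern.
    """
    roles: dict[str, ColumnRole] = {}
    for name in columns:
        low = str(name).lower()
        if ADJUSTED_RE.search(low) or QVALUE_RE.search(low):
            roles[name] = ColumnRole("adjusted")
        elif PVALUE_RE.search(low):
            roles[name] = ColumnRole("pvalue")
        else:
            matches = [p for p in EXPRESSION_PATTERNS if p in low]
            if matches:
                metric = max(matches, key=len)
                roles[name] = ColumnRole("expression", metric=metric)
            else:
                roles[name] = ColumnRole("other")
    return roles


def find_pvalue_columns(table: ProcessedTable) -> list[str]:
    """Columns holding unadjusted p-values (p-val pattern minus adjusted)."""
    return table.columns_with_role("pvalue")


def find_expression_columns(table: ProcessedTable) -> list[tuple[str, str]]:
    """Columns holding expression-level metrics, as (name, metric) pairs."""
    return [(c, table.roles[c].metric or "") for c in table.columns_with_role("expression")]


def filename_passes_prefilter(filename: str) -> bool:
    """Whether a supplementary file name is worth reading for p-values.

    False when the lower-cased name matches the drop pattern (series
    matrices, alignments, sequences, coverage tracks, ...) or when its
    extension (ignoring a trailing .gz) is not an accepted tabular format.
    """
    if not filename:
        raise ValueError("empty filename")
    low = Path(filename).name.lower()
    if DROP_FILENAME_RE.search(low):
        return False
    stem = low[:-3] if low.endswith(".gz") else low
    ext = stem.rsplit(".", 1)[-1] if "." in stem else ""
    return ext in ACCEPTED_EXTENSIONS


def _sniff_delimiter(sample: str) -> str | None:
    first = next((ln for ln in sample.splitlines() if ln.strip()), "")
    counts = {d: first.count(d) for d in ("\t", ",", ";")}
    best = max(counts, key=counts.__getitem__)
    return best if counts[best] > 0 else None


def read_table(path) -> ProcessedTable:
    """Parse a delimited (or .xlsx) table, transparently decompressing gzip.

    The delimiter is sniffed among tab, comma and semicolon from the header
    line; a header row is required. Cells are kept as parsed; numeric
    coercion to NaN happens on access via :meth:`ProcessedTable.numeric`.

    Raises
    ------
    TableImportError
        Undecodable text, no detectable delimiter, or unsupported binary
        format. Use :func:`try_read_table` for a non-raising variant.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    low = path.name.lower()
    if low.endswith((".xlsx", ".xlsx.gz")):
        try:
            df = pd.read_excel(path, engine="openpyxl")
        except Exception as exc:  # malformed/binary
            raise TableImportError(f"{path}: cannot read xlsx ({exc})") from exc
        return ProcessedTable(df=df, source_path=str(path))
    if low.endswith((".xls", ".rtf", ".tar", ".tar.gz")):
        raise TableImportError(f"{path}: unsupported format")
    try:
        opener = gzip.open if low.endswith(".gz") else open
        with opener(path, "rt", encoding="utf-8") as fh:
            text = fh.read()
    except (UnicodeDecodeError, OSError, EOFError) as exc:
        raise TableImportError(f"{path}: undecodable text ({exc})") from exc
    delim = _sniff_delimiter(text[:65536])
    if delim is None:
        raise TableImportError(f"{path}: no detectable delimiter")
    try:
        df = pd.read_csv(io.StringIO(text), sep=delim, quoting=csv.QUOTE_MINIMAL)
    except Exception as exc:
        raise TableImportError(f"{path}: parse failure ({exc})") from exc
    if df.columns.size == 0:
        raise TableImportError(f"{path}: empty table")
    return ProcessedTable(df=df, source_path=str(path), meta={"delimiter": delim})


def try_read_table(path) -> tuple[ProcessedTable | None, str | None]:
    """Like :func:`read_table` but returns (table, None) or (None, reason)."""
    try:
        return read_table(path), None
    except TableImportError as exc:
        return None, str(exc)


def validate_pvalue_set(
    values,
    truncated_max: float = 0.9,
    skew_alpha: float = 1e-3,
) -> ValidationVerdict:
    """Screen a candidate p-value set for disqualifying defects.

    In order: ``all_nan`` when no finite values remain; ``out_of_range``
    when any finite value falls outside [0, 1]; ``truncated`` when the
    largest finite value is below ``truncated_max`` (significant-only
    exports); ``right_skewed`` when the last decile holds significantly
    more mass than the first (one-sided binomial test at ``skew_alpha``)
    AND the last decile bin is the global maximum (1 - p transforms,
    score columns); otherwise ``ok``.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return ValidationVerdict("all_nan", "no finite values")
    if finite.min() < 0 or finite.max() > 1:
        return ValidationVerdict(
            "out_of_range", f"values span [{finite.min():g}, {finite.max():g}]")
    if finite.max() < truncated_max:
        return ValidationVerdict("truncated", f"max p = {finite.max():g}")
    deciles, _ = np.histogram(finite, bins=np.arange(11) / 10)
    c_first, c_last = int(deciles[0]), int(deciles[-1])
    if c_last == deciles.max() and c_first + c_last > 0:
        p_skew = stats.binomtest(
            c_last, c_first + c_last, 0.5, alternative="greater").pvalue
        if p_skew < skew_alpha:
            return ValidationVerdict(
                "right_skewed",
                f"last decile {c_last} vs first {c_first} (p={p_skew:.2e})")
    return ValidationVerdict("ok")


def _normalize_tool_token(token: str) -> str:
    token = token.strip()
    aliases = {
        "cufflinks": "cuffdiff",
        "voom": "limma",
        "nascent rna seq": "nrsa",
        "clcbio genomics": "clc genomics",
    }
    return aliases.get(token, token)


def infer_de_tool(
    table: ProcessedTable | None = None,
    pub_date: date | str | None = None,
    free_text: str | None = None,
) -> DEToolLabel:
    """Infer the differential-expression analysis tool behind a table.

    Free-text evidence (the tool-name pattern applied to lower-cased text)
    takes precedence over column-name heuristics. Column heuristics:
    fpkm-scale expression plus a ``p_value`` column -> cuffdiff; basemean
    plus ``pval`` -> deseq; basemean plus ``pvalue`` -> deseq2; logcpm ->
    edger; aveexpr plus ``p.value`` with publication after 2014-01-01 ->
    limma; otherwise unknown. cuffdiff's FPKM columns are conventionally
    named value_1/value_2, so the "value" metric counts as fpkm-scale here.
    """
    if free_text:
        m = TOOL_TEXT_RE.search(free_text.lower())
        if m:
            return DEToolLabel(_normalize_tool_token(m.group(0)), "text_regex")
    if table is not None:
        metrics = {r.metric for r in table.roles.values() if r.role == "expression"}
        pnames = {str(c).lower() for c in table.columns_with_role("pvalue")}
        if isinstance(pub_date, str):
            pub_date = date.fromisoformat(pub_date)
        if metrics & {"fpkm", "value"} and "p_value" in pnames:
            return DEToolLabel("cuffdiff", "column_heuristic")
        if "basemean" in metrics and "pval" in pnames:
            return DEToolLabel("deseq", "column_heuristic")
        if "basemean" in metrics and "pvalue" in pnames:
            return DEToolLabel("deseq2", "column_heuristic")
        if "logcpm" in metrics:
            return DEToolLabel("edger", "column_heuristic")
        if ("aveexpr" in metrics and "p.value" in pnames
                and pub_date is not None and pub_date > date(2014, 1, 1)):
            return DEToolLabel("limma", "column_heuristic")
    return DEToolLabel("unknown", "column_heuristic")


def determine_sample_size(n_samples: int, n_pvalue_sets: int) -> SampleSizeRecord:
    """Per-group sample size under the balanced-design rule.

    Divides the number of samples by (number of p-value sets + 1); the
    per-group n is defined only when the division is exact (balanced
    design), else left undefined.
    """
    if n_samples < 1 or n_pvalue_sets < 1:
        raise ValueError("n_samples and n_pvalue_sets must be positive")
    groups = n_pvalue_sets + 1
    per = n_samples // groups if n_samples % groups == 0 else None
    return SampleSizeRecord(n_samples, n_pvalue_sets, per)
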