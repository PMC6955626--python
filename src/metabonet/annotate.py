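"""Joining expression, prognosis and biofluid tables onto network nodes.

Three tabular layers, emulating tissue-expression exports (Human Protein
Atlas style), pathology prognosis exports (direction + log-rank p-value
from Kaplan-Meier analysis of patient survival) and metabolite
biofluid-detectability records (Human Metabolome Database style), are
joined onto nodes as attributes.  Matching is exact on the canonical
namespaced id — silent fuzzy mis-joins are worse than reported misses —
and every call returns a :class:`JoinReport` accounting for each input
row.  Annotation never adds or removes nodes or edges.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .network import MetaboNetwork, NODE_METABOLITE

logger = logging.getLogger(__name__)

PROGNOSIS_DIRECTIONS = frozenset({"favorable", "unfavorable"})
PROGNOSIS_NONE = "none"

_BOOL_VALUES = {"true": True, "false": False}


class AnnotationError(ValueError):
    """Raised for malformed annotation tables or colliding joins."""


@dataclass(frozen=True)
class JoinReport:
    """Accounting for one annotation join: every row is matched or listed."""

    matched: int
    unmatched_ids: tuple[str, ...]

    @property
    def total(self) -> int:
        return self.matched + len(self.unmatched_ids)


@dataclass(frozen=True)
class AnnotationTables:
    """The three annotation layers as validated DataFrames."""

    expression: pd.DataFrame
    prognosis: pd.DataFrame
    biofluid: pd.DataFrame


def _read_tsv(source, columns: tuple[str, ...]) -> pd.DataFrame:
    if isinstance(source, str) and "\n" in source:  # inline TSV text
        df = pd.read_csv(io.StringIO(source), sep="\t", dtype=str)
    else:  # path or file-like
        df = pd.read_csv(source, sep="\t", dtype=str)
    missing = set(columns) - set(df.columns)
    if missing:
        raise AnnotationError(f"table is missing column(s): {sorted(missing)}")
    return df.loc[:, list(columns)]


def _parse_bool(value: str, context: str) -> bool:
    try:
        return _BOOL_VALUES[str(value).strip().lower()]
    except KeyError:
        raise AnnotationError(f"{context}: expected true/false, got {value!r}") from None


def read_expression_table(source) -> pd.DataFrame:
    """Read a TSV of (gene_id, tissue, value); value must be >= 0."""
    df = _read_tsv(source, ("gene_id", "tissue", "value"))
    df["value"] = df["value"].astype(float)
    if (df["value"] < 0).any():
        raise AnnotationError("expression values must be non-negative")
    return df


def read_prognosis_table(source) -> pd.DataFrame:
    """Read a TSV of (gene_id, direction, logrank_p)."""
    df = _read_tsv(source, ("gene_id", "direction", "logrank_p"))
    bad = set(df["direction"]) - PROGNOSIS_DIRECTIONS
    if bad:
        raise AnnotationError(f"unknown prognosis direction(s): {sorted(bad)}")
    df["logrank_p"] = df["logrank_p"].astype(float)
    if ((df["logrank_p"] <= 0) | (df["logrank_p"] > 1)).any():
        raise AnnotationError("logrank_p must be in (0, 1]")
    return df


def read_biofluid_table(source) -> pd.DataFrame:
    """Read a TSV of (metabolite_id, in_normal_urine, in_abnormal_urine)."""
    df = _read_tsv(source, ("metabolite_id", "in_normal_urine", "in_abnormal_urine"))
    for col in ("in_normal_urine", "in_abnormal_urine"):
        df[col] = [
            _parse_bool(v, f"biofluid {col}") for v in df[col]
        ]
    if df["metabolite_id"].duplicated().any():
        dupes = sorted(df.loc[df["metabolite_id"].duplicated(), "metabolite_id"])
        raise AnnotationError(f"duplicate biofluid record(s) for: {dupes}")
    return df


def load_annotation_tables(
    expression_path, prognosis_path, biofluid_path
) -> AnnotationTables:
    return AnnotationTables(
        expression=read_expression_table(expression_path),
        prognosis=read_prognosis_table(prognosis_path),
        biofluid=read_biofluid_table(biofluid_path),
    )


def annotate_expression(
    network: MetaboNetwork,
    records: pd.DataFrame,
    tissue: str = "hepatocytes",
    alias_map: Mapping[str, str] | None = None,
) -> tuple[MetaboNetwork, JoinReport]:
    """Attach ``expression_value`` to gene nodes from tissue-matched rows.

    ``alias_map`` optionally maps record symbols to canonical node ids.
    Duplicate (gene_id, tissue) rows with conflicting values raise
    :class:`AnnotationError`.
    """
    rows = records[records["tissue"] == tissue]
    resolved = [
        (alias_map.get(g, g) if alias_map else g, float(v))
        for g, v in zip(rows["gene_id"], rows["value"])
    ]
    seen: dict[str, float] = {}
    conflicts = []
    for gid, value in resolved:
        if gid in seen and seen[gid] != value:
            conflicts.append(gid)
        seen[gid] = value
    if conflicts:
        raise AnnotationError(
            f"conflicting expression values in tissue {tissue!r} for: "
            + ", ".join(sorted(set(conflicts)))
        )
    out = network.copy()
    genes = out.gene_ids
    unmatched = []
    for gid, value in sorted(seen.items()):
        if gid in genes:
            out.graph.nodes[gid]["expression_value"] = value
        else:
            unmatched.append(gid)
    report = JoinReport(matched=len(seen) - len(unmatched), unmatched_ids=tuple(unmatched))
    if unmatched:
        logger.info("expression join: %d unmatched id(s)", len(unmatched))
    return out, report


def annotate_prognosis(
    network: MetaboNetwork,
    records: pd.DataFrame,
    alpha: float = 0.001,
    alias_map: Mapping[str, str] | None = None,
) -> tuple[MetaboNetwork, JoinReport]:
    """Attach ``prognosis`` and ``prognosis_p`` to gene nodes.

    A gene is labelled with its record's direction iff its log-rank
    p-value is strictly below ``alpha``; otherwise it is labelled
    ``"none"``.  The p-value itself is recorded either way.
    """
    if not 0 < alpha <= 1:
        raise AnnotationError("alpha must be in (0, 1]")
    bad = set(records["direction"]) - PROGNOSIS_DIRECTIONS
    if bad:
        raise AnnotationError(f"unknown prognosis direction(s): {sorted(bad)}")
    out = network.copy()
    genes = out.gene_ids
    matched = 0
    unmatched = []
    for _, row in records.iterrows():
        gid = row["gene_id"]
        if alias_map:
            gid = alias_map.get(gid, gid)
        p = float(row["logrank_p"])
        if gid not in genes:
            unmatched.append(gid)
            continue
        node = out.graph.nodes[gid]
        node["prognosis"] = row["direction"] if p < alpha else PROGNOSIS_NONE
        node["prognosis_p"] = p
        matched += 1
    return out, JoinReport(matched=matched, unmatched_ids=tuple(sorted(unmatched)))


def annotate_biofluid(
    network: MetaboNetwork, records: pd.DataFrame
) -> tuple[MetaboNetwork, JoinReport]:
    """Attach urine detectability booleans to metabolite nodes.

    A record whose id collides with a gene node raises
    :class:`AnnotationError`; metabolites without a record keep their
    attributes absent (absence of evidence is not negative evidence).
    """
    out = network.copy()
    genes = out.gene_ids
    metabolites = out.metabolite_ids
    matched = 0
    unmatched = []
    for _, row in records.iterrows():
        mid = row["metabolite_id"]
        if mid in genes:
            raise AnnotationError(
                f"biofluid record id {mid!r} collides with a gene node"
            )
        if mid not in metabolites:
            unmatched.append(mid)
            continue
        node = out.graph.nodes[mid]
        node["urine_normal"] = bool(row["in_normal_urine"])
        node["urine_abnormal"] = bool(row["in_abnormal_urine"])
        matched += 1
    return out, JoinReport(matched=matched, unmatched_ids=tuple(sorted(unmatched)))
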