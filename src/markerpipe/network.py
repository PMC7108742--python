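"""Interaction-network integration of differential-expression results.

Local interaction tables (STRING protein-protein exports, miRTarBase /
TargetScan miRNA-target exports) are joined with DEA calls: protein-protein
pairs are kept when both members are differentially expressed; miRNA-gene
pairs when both members are significant with inverse-signed fold changes.
Edges are ranked by interaction score times mean absolute logFC and the
top-N exported alongside the full annotated table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_meta import ValidationError

DIALECTS = ("string_pp", "mirna_targets")


@dataclass
class Edge:
    id_a: str
    id_b: str
    score: float
    type: str                       # "pp" | "mirna_gene"


@dataclass
class InteractionSet:
    """Typed scored edges annotated with both members' DEA statistics."""

    edges: pd.DataFrame             # id_a, id_b, score, type, logFC_a, FDR_a, logFC_b, FDR_b
    n_skipped_rows: int = 0

    def __post_init__(self) -> None:
        if len(self.edges):
            s = self.edges["score"]
            if ((s < 0) | (s > 1)).any():
                raise ValidationError("interaction scores must lie in [0, 1]")
            mg = self.edges[self.edges["type"] == "mirna_gene"]
            if len(mg) and not (np.sign(mg["logFC_a"]) * np.sign(mg["logFC_b"]) < 0).all():
                raise ValidationError("miRNA-gene edges must have inverse-signed logFCs")


def load_interaction_table(
    path: str | Path,
    dialect: str,
    alias: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Read a local interaction export into a normalized edge list.

    string_pp: whitespace/tab table with two identifier columns and an
    integer combined score 0-1000 (scaled into [0,1]). mirna_targets: table
    with a mature miRNA column, a target gene column, and an optional support
    type (validated targets score 1.0, predicted 0.5, otherwise 1.0).
    Duplicate undirected edges collapse to the maximum score; rows with
    malformed scores are skipped and counted. ``alias`` maps identifiers to
    canonical names (exact, case-preserving).
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"dialect must be one of {DIALECTS}")
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = list(table.columns)
    skipped = 0
    rows = []
    if dialect == "string_pp":
        if len(cols) < 3:
            raise ValidationError(
                f"string_pp table needs two identifier columns and a combined "
                f"score; header was {cols}"
            )
        for _, row in table.iterrows():
            a, b, raw = str(row[cols[0]]), str(row[cols[1]]), row[cols[2]]
            try:
                score = float(raw) / 1000.0
            except (TypeError, ValueError):
                skipped += 1
                continue
            if not 0.0 <= score <= 1.0:
                skipped += 1
                continue
            rows.append((a, b, score))
        etype = "pp"
    else:
        if len(cols) < 2:
            raise ValidationError(
                f"mirna_targets table needs miRNA and target columns; header was {cols}"
            )
        support_col = cols[2] if len(cols) > 2 else None
        for _, row in table.iterrows():
            a, b = str(row[cols[0]]), str(row[cols[1]])
            if a in ("nan", "") or b in ("nan", ""):
                skipped += 1
                continue
            score = 1.0
            if support_col is not None:
                support = str(row[support_col]).lower()
                if "predict" in support:
                    score = 0.5
            rows.append((a, b, score))
        etype = "mirna_gene"

    alias = alias or {}
    norm: dict[tuple[str, str], float] = {}
    for a, b, score in rows:
        a, b = alias.get(a, a), alias.get(b, b)
        key = (min(a, b), max(a, b)) if etype == "pp" else (a, b)
        norm[key] = max(norm.get(key, 0.0), score)
    edges = pd.DataFrame(
        [{"id_a": k[0], "id_b": k[1], "score": v, "type": etype} for k, v in sorted(norm.items())]
    )
    return edges, skipped


def _annotate(edges: pd.DataFrame, stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> pd.DataFrame:
    sa = stats_a.set_index("id")
    sb = stats_b.set_index("id")
    out = edges.copy()
    out["logFC_a"] = [float(sa.loc[i, "logFC"]) for i in out["id_a"]]
    out["FDR_a"] = [float(sa.loc[i, "adj.P.Val"]) for i in out["id_a"]]
    out["logFC_b"] = [float(sb.loc[i, "logFC"]) for i in out["id_b"]]
    out["FDR_b"] = [float(sb.loc[i, "adj.P.Val"]) for i in out["id_b"]]
    return out


def extract_de_pairs(
    edges: pd.DataFrame, dea_table: pd.DataFrame, sig_ids: set[str]
) -> InteractionSet:
    """Protein-protein edges where both endpoints are differentially expressed."""
    if len(edges) == 0:
        return InteractionSet(_empty_edges())
    keep = edges[edges["id_a"].isin(sig_ids) & edges["id_b"].isin(sig_ids)]
    if len(keep) == 0:
        return InteractionSet(_empty_edges())
    return InteractionSet(_annotate(keep.reset_index(drop=True), dea_table, dea_table))


def integrate_inverse_pairs(
    mirna_edges: pd.DataFrame,
    mirna_dea: pd.DataFrame,
    gene_dea: pd.DataFrame,
    mirna_sig: set[str],
    gene_sig: set[str],
) -> InteractionSet:
    """miRNA-gene edges with both members significant and inverse fold changes."""
    if len(mirna_edges) == 0:
        return InteractionSet(_empty_edges())
    keep = mirna_edges[
        mirna_edges["id_a"].isin(mirna_sig) & mirna_edges["id_b"].isin(gene_sig)
    ].reset_index(drop=True)
    if len(keep) == 0:
        return InteractionSet(_empty_edges())
    ann = _annotate(keep, mirna_dea, gene_dea)
    inverse = np.sign(ann["logFC_a"]) * np.sign(ann["logFC_b"]) < 0
    ann = ann[inverse].reset_index(drop=True)
    return InteractionSet(ann if len(ann) else _empty_edges())


def rank_edges(
    interactions: InteractionSet, top_n: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank by strength = score * (|logFC_a| + |logFC_b|)/2, ties broken
    lexicographically by (id_a, id_b); returns (top table, full table)."""
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    full = interactions.edges.copy()
    if len(full) == 0:
        full["strength"] = pd.Series(dtype=float)
        return full, full
    full["strength"] = full["score"] * (full["logFC_a"].abs() + full["logFC_b"].abs()) / 2.0
    full = full.sort_values(
        by=["strength", "id_a", "id_b"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return full.head(top_n).copy(), full


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["id_a", "id_b", "score", "type", "logFC_a", "FDR_a", "logFC_b", "FDR_b"]
    )
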