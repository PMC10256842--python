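"""Structural prioritization of candidate off-target proteins.

Two complementary comparisons against a reference enzyme (the drug's intended
target): global similarity of whole-chain structural properties (size,
surface, secondary-structure content, ...) via Pearson correlation of
standardized property vectors, and local similarity of binding clefts via the
Tanimoto coefficient over binding-pocket interaction fingerprints.  Pocket
detection and whole-structure alignment are upstream tools; their outputs
(property tables, fingerprint bit sets, optional alignment p-values) are the
inputs here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "global_similarity_matrix",
    "select_top_pockets",
    "pocket_tanimoto",
    "rank_candidates",
    "parse_bits",
]


def parse_bits(bits) -> frozenset:
    """Fingerprint bit set from an iterable or space-separated string."""
    if isinstance(bits, str):
        return frozenset(int(b) for b in bits.split())
    return frozenset(int(b) for b in bits)


def global_similarity_matrix(properties: pd.DataFrame) -> pd.DataFrame:
    """Protein x protein Pearson correlation of z-scored property vectors.

    Each property is standardized across proteins first, so heterogeneous
    units cannot dominate; zero-variance properties are dropped with a
    warning.
    """
    if len(properties) < 2 or properties.shape[1] < 2:
        raise ValueError("need >= 2 proteins and >= 2 properties")
    sd = properties.std(ddof=0)
    dead = sd[sd == 0].index
    if len(dead):
        warnings.warn(f"dropping zero-variance properties: {list(dead)}")
        properties = properties.drop(columns=dead)
        sd = sd.drop(index=dead)
    z = (properties - properties.mean()) / sd
    return z.T.corr(method="pearson")


def select_top_pockets(pockets: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Per protein, keep the k largest pockets by size.

    Size ties at the cut break by lexicographically smaller pocket id.
    Expects columns protein_id, pocket_id, size, bits.
    """
    ordered = pockets.sort_values(["protein_id", "size", "pocket_id"],
                                  ascending=[True, False, True])
    return (ordered.groupby("protein_id", group_keys=False)
            .head(k).reset_index(drop=True))


def pocket_tanimoto(a, b) -> float:
    """Tanimoto coefficient |a&b| / |a|b| of two fingerprint bit sets."""
    a, b = parse_bits(a), parse_bits(b)
    union = a | b
    if not union:
        raise ValueError("Tanimoto undefined for two empty bit sets")
    return len(a & b) / len(union)


def rank_candidates(
    reference: str,
    candidates,
    pockets: pd.DataFrame,
    pathway_membership: dict[str, str] | None = None,
    alignment_pvalues: pd.DataFrame | None = None,
    k: int = 5,
    aggregate: str = "max",
) -> pd.DataFrame:
    """Score candidates by pocket-fingerprint similarity to the reference.

    Each candidate's score is the max (or mean) pairwise Tanimoto between its
    retained top-k pockets and the reference's.  Candidates with no pockets
    score 0 and are flagged.  Optional whole-structure alignment p-values
    (columns protein_a, protein_b, p) are merged for context, not used in the
    score.
    """
    kept = select_top_pockets(pockets, k)
    by_protein = {pid: [parse_bits(b) for b in grp["bits"]]
                  for pid, grp in kept.groupby("protein_id")}
    ref_pockets = by_protein.get(reference, [])
    if not ref_pockets:
        raise ValueError(f"reference {reference!r} has no retained pockets")
    if aggregate not in ("max", "mean"):
        raise ValueError("aggregate must be 'max' or 'mean'")

    pvals = {}
    if alignment_pvalues is not None:
        for _, row in alignment_pvalues.iterrows():
            pvals[frozenset((row["protein_a"], row["protein_b"]))] = row["p"]

    rows = []
    for cand in candidates:
        cand_pockets = by_protein.get(cand, [])
        if not cand_pockets:
            rows.append({"protein_id": cand, "pocket_score": 0.0,
                         "no_pockets": True})
            continue
        sims = [pocket_tanimoto(a, b) for a in cand_pockets for b in ref_pockets]
        score = max(sims) if aggregate == "max" else float(np.mean(sims))
        rows.append({"protein_id": cand, "pocket_score": score,
                     "no_pockets": False})
    out = pd.DataFrame(rows)
    if pathway_membership is not None:
        out["pathway"] = out["protein_id"].map(pathway_membership).fillna("other")
    if pvals:
        out["alignment_p"] = [
            pvals.get(frozenset((reference, c)), np.nan) for c in out["protein_id"]
        ]
    out = out.sort_values(["pocket_score", "protein_id"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
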