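"""Protein inference and peptide-to-protein abundance roll-up.

Inference follows the post-search reporting rules used for shotgun
proteomes: proteins matching an identical peptide set are merged into a
metaprotein, peptides shared between distinct metaproteins are discarded,
and metaproteins left with fewer than two peptides are dropped (the
two-peptide rule). Quantitative roll-up rescales member peptide profiles to
a common level and takes their per-sample median.

The degradome (<5 kDa endogenous-peptide) branch of the pipeline bypasses
this module entirely: it is quantified at peptide level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PeptideRecord, QuantMatrix


# ---------------------------------------------------------------------------
# Target-decoy identification FDR
# ---------------------------------------------------------------------------

def threshold_decoy_fdr(
    psm_scores: list[tuple[float, bool]], target_fdr: float
) -> tuple[float, list[int]]:
    """Score threshold controlling the target-decoy identification FDR.

    ``psm_scores`` is a list of ``(score, is_decoy)``. Returns the smallest
    observed-score threshold ``t`` such that
    ``#decoys(score >= t) / #targets(score >= t) <= target_fdr``, together
    with the indices of accepted (target, score >= t) entries. If no
    threshold attains the FDR, returns ``(inf, [])`` with a warning.
    """
    if not (0.0 < target_fdr < 1.0):
        raise ValueError("target_fdr must lie in (0, 1)")
    scores = np.array([s for s, _ in psm_scores], float)
    decoy = np.array([d for _, d in psm_scores], bool)
    if not (~decoy).any():
        raise ValueError("no target entries")
    best_t = None
    for t in np.unique(scores):  # ascending: first passing t is the smallest
        sel = scores >= t
        n_tgt = int((sel & ~decoy).sum())
        n_dec = int((sel & decoy).sum())
        if n_tgt > 0 and n_dec / n_tgt <= target_fdr:
            best_t = float(t)
            break
    if best_t is None:
        warnings.warn("no score threshold attains the requested FDR; accepting nothing")
        return float("inf"), []
    accepted = [i for i, (s, d) in enumerate(psm_scores) if not d and s >= best_t]
    return best_t, accepted


# ---------------------------------------------------------------------------
# Metaprotein inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metaprotein:
    """Cluster of protein accessions indistinguishable by their peptide set."""

    member_accessions: tuple[str, ...]
    peptide_ids: frozenset[str]

    @property
    def id(self) -> str:
        return "|".join(self.member_accessions)


def infer_proteins(
    peptides: list[PeptideRecord], min_peptides: int = 2
) -> tuple[list[Metaprotein], dict[str, str]]:
    """Apply the metaprotein / shared-peptide / two-peptide rules.

    1. Proteins matched by identical peptide sets merge into one metaprotein.
    2. Peptides matching more than one metaprotein are discarded (peptides
       shared only among the merged, indistinguishable members survive).
    3. Metaproteins left with fewer than ``min_peptides`` peptides are
       discarded.

    Returns the surviving metaproteins (sorted by id) and the
    peptide_id -> metaprotein_id map over exactly the surviving peptides.
    """
    prot2peps: dict[str, set[str]] = {}
    for p in peptides:
        for acc, _, _ in p.matches:
            prot2peps.setdefault(acc, set()).add(p.peptide_id)

    by_pepset: dict[frozenset[str], list[str]] = {}
    for acc, peps in prot2peps.items():
        by_pepset.setdefault(frozenset(peps), []).append(acc)

    metas = [
        Metaprotein(tuple(sorted(accs)), pepset) for pepset, accs in by_pepset.items()
    ]

    pep_meta_count: dict[str, int] = {}
    for m in metas:
        for pid in m.peptide_ids:
            pep_meta_count[pid] = pep_meta_count.get(pid, 0) + 1
    shared = {pid for pid, c in pep_meta_count.items() if c > 1}

    survivors: list[Metaprotein] = []
    mapping: dict[str, str] = {}
    for m in metas:
        kept = frozenset(m.peptide_ids - shared)
        if len(kept) < min_peptides:
            continue
        mm = Metaprotein(m.member_accessions, kept)
        survivors.append(mm)
        for pid in kept:
            mapping[pid] = mm.id
    survivors.sort(key=lambda m: m.id)
    return survivors, mapping


def metaprotein_table(metas: list[Metaprotein]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metaprotein_id": [m.id for m in metas],
            "members": [";".join(m.member_accessions) for m in metas],
            "n_peptides": [len(m.peptide_ids) for m in metas],
        }
    )


# ---------------------------------------------------------------------------
# Quantitative roll-up
# ---------------------------------------------------------------------------

def rollup_proteins(
    m: QuantMatrix, pep_to_meta: dict[str, str]
) -> QuantMatrix:
    """Roll peptide-level log2 abundances up to metaprotein level.

    Per metaprotein: each member peptide's profile is shifted so that its
    across-sample median equals the reference level (the median of the member
    peptides' medians); the protein abundance in a sample is the median of
    the shifted peptide values present there. Samples with no member peptide
    present stay missing. The result is invariant to per-peptide constant
    log-offsets (ionization-efficiency surrogates).
    """
    if m.scale != "log2":
        raise ValueError("rollup expects a log2-scale matrix")
    missing = set(pep_to_meta) - set(m.feature_ids)
    if missing:
        raise ValueError(f"mapped peptides absent from matrix: {sorted(missing)[:5]}")

    groups: dict[str, list[str]] = {}
    for pid, mid in pep_to_meta.items():
        groups.setdefault(mid, []).append(pid)

    rows = {}
    for mid in sorted(groups):
        pids = sorted(groups[mid])
        block = m.data.loc[pids]
        med = block.median(axis=1, skipna=True)
        reference = float(np.nanmedian(med.to_numpy()))
        shifted = block.sub(med - reference, axis=0)
        rows[mid] = shifted.median(axis=0, skipna=True)

    out = pd.DataFrame(rows).T
    out.index.name = "feature_id"
    return QuantMatrix(out.reindex(columns=m.sample_ids), scale="log2")
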