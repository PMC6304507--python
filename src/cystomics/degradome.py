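"""Degradome analytics: peptide mapping, cleavage-site flank windows and
sequence logos, exopeptidase ladder detection, protein coverage maps, and
per-group peptide/protein uniqueness counts.

Protease nomenclature: the cleavage occurs between P1 and P1'; P4..P1 lie
N-terminal of the scissile bond, P1'..P4' C-terminal. A peptide observed at
protein positions [start, end] witnesses one cleavage at its N-terminus
(between residues start-1 and start) and one at its C-terminus (between
end and end+1); windows running past a protein end are padded with '-'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .io import CANONICAL_AA, GAP, PeptideRecord, ProteinDB, QuantMatrix

N_ALPHABET = len(CANONICAL_AA)  # 20
MAX_BITS = float(np.log2(N_ALPHABET))


def position_labels(width: int = 4) -> list[str]:
    return [f"P{i}" for i in range(width, 0, -1)] + [f"P{i}'" for i in range(1, width + 1)]


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def map_peptides(
    sequences: list[str], db: ProteinDB
) -> tuple[list[PeptideRecord], list[str]]:
    """Exact substring search of each peptide against every protein.

    All occurrences are recorded (multiple proteins, multiple sites).
    Returns the records plus the list of unmapped sequences.
    """
    records, unmapped = [], []
    for i, seq in enumerate(sequences):
        matches: list[tuple[str, int, int]] = []
        for acc, prot in db.items():
            pos = prot.find(seq)
            while pos != -1:
                matches.append((acc, pos + 1, pos + len(seq)))
                pos = prot.find(seq, pos + 1)
        rec = PeptideRecord(f"pep{i + 1:05d}", seq, matches)
        records.append(rec)
        if not matches:
            unmapped.append(seq)
    return records, unmapped


# ---------------------------------------------------------------------------
# Flank windows and logos
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlankWindow:
    """Residues around one observed cleavage site (P4..P1, P1'..P4' by
    default); '-' marks positions beyond the protein ends."""

    terminus: str                       # which peptide terminus: "N" or "C"
    residues: tuple[str, ...]
    source: tuple[str, str, int]        # (peptide_id, accession, cut position)


def _window(seq: str, lo: int, hi: int) -> tuple[str, ...]:
    """Residues at 1-based positions lo..hi with '-' outside 1..len."""
    return tuple(seq[p - 1] if 1 <= p <= len(seq) else GAP for p in range(lo, hi + 1))


def extract_flanks(
    rec: PeptideRecord, db: ProteinDB, width: int = 4
) -> list[tuple[FlankWindow, FlankWindow]]:
    """Per match, the N-terminal and C-terminal cleavage windows.

    For a peptide at [start, end], the N window spans protein positions
    start-width .. start+width-1 (P1 = residue start-1, P1' = residue start)
    and the C window spans end-width+1 .. end+width.
    """
    out = []
    for acc, start, end in rec.matches:
        seq = db[acc]
        n_win = FlankWindow(
            "N", _window(seq, start - width, start + width - 1),
            (rec.peptide_id, acc, start - 1),
        )
        c_win = FlankWindow(
            "C", _window(seq, end - width + 1, end + width),
            (rec.peptide_id, acc, end),
        )
        out.append((n_win, c_win))
    return out


def collect_flank_windows(
    records: list[PeptideRecord],
    db: ProteinDB,
    width: int = 4,
    unique_matches_only: bool = False,
) -> tuple[list[FlankWindow], list[FlankWindow]]:
    """All N- and C-terminal windows over a peptide collection. With
    ``unique_matches_only`` peptides matching several proteins are skipped."""
    n_windows, c_windows = [], []
    for rec in records:
        if not rec.matches:
            continue
        if unique_matches_only and len({m[0] for m in rec.matches}) > 1:
            continue
        for n_win, c_win in extract_flanks(rec, db, width):
            n_windows.append(n_win)
            c_windows.append(c_win)
    return n_windows, c_windows


@dataclass
class LogoMatrix:
    """Per-position amino-acid composition around cleavage sites.

    ``counts`` and ``freqs`` are position x residue frames (gap positions are
    excluded from normalization); ``info_bits`` is log2(20) minus the Shannon
    entropy of each position's residue distribution.
    """

    counts: pd.DataFrame
    freqs: pd.DataFrame
    info_bits: pd.Series

    @property
    def positions(self) -> list[str]:
        return list(self.counts.index)


def build_logo(
    windows: list[FlankWindow], weights: dict[str, float] | None = None
) -> LogoMatrix:
    """Count-based logo matrix (each window counts once; pass per-peptide
    ``weights`` keyed by peptide_id for abundance weighting)."""
    if not windows:
        raise ValueError("cannot build a logo from zero windows")
    width = len(windows[0].residues) // 2
    labels = position_labels(width)
    counts = pd.DataFrame(0.0, index=labels, columns=list(CANONICAL_AA))
    for w in windows:
        wt = 1.0 if weights is None else float(weights.get(w.source[0], 0.0))
        for pos, aa in zip(labels, w.residues):
            if aa != GAP:
                counts.loc[pos, aa] += wt
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    f = freqs.to_numpy()
    logf = np.zeros_like(f)
    np.log2(f, out=logf, where=f > 0)
    entropy = -(f * logf).sum(axis=1)
    info = pd.Series(MAX_BITS - entropy, index=labels).clip(lower=0.0)
    info[totals == 0] = 0.0
    return LogoMatrix(counts, freqs, info)


def logo_divergence(a: LogoMatrix, b: LogoMatrix) -> pd.Series:
    """Per-position Jensen–Shannon divergence (base 2, squared distance)
    between two logos — the computational analog of comparing group logos."""
    out = {}
    for pos in a.positions:
        p = a.freqs.loc[pos].to_numpy()
        q = b.freqs.loc[pos].to_numpy()
        if p.sum() == 0 or q.sum() == 0:
            out[pos] = 0.0
        else:
            out[pos] = float(jensenshannon(p, q, base=2) ** 2)
    return pd.Series(out)


def plot_logo(logo: LogoMatrix, path: str, title: str = "") -> None:
    """Minimal information-content bar rendering of a logo matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    pos = np.arange(len(logo.positions))
    bottom = np.zeros(len(pos))
    for aa in CANONICAL_AA:
        h = logo.freqs[aa].to_numpy() * logo.info_bits.to_numpy()
        ax.bar(pos, h, bottom=bottom, label=aa)
        bottom += h
    ax.set_xticks(pos, logo.positions)
    ax.set_ylabel("bits")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Ladders
# ---------------------------------------------------------------------------

@dataclass
class Ladder:
    """Nested peptide series sharing one terminus — the exopeptidase
    signature. ``shared_terminus`` names the fixed terminus ('N' means all
    members share the start coordinate and are trimmed at the C side)."""

    accession: str
    shared_terminus: str          # "N" or "C" (the FIXED terminus)
    coordinate: int               # the shared start (N) or end (C) position
    members: list[str]            # peptide ids, longest first
    lengths: list[int]
    steps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.steps = [a - b for a, b in zip(self.lengths[:-1], self.lengths[1:])]


def detect_ladders(
    records: list[PeptideRecord], min_rungs: int = 3
) -> list[Ladder]:
    """Group peptide matches by shared N-terminus (trimming at C) and shared
    C-terminus (trimming at N); emit groups with >= min_rungs distinct
    lengths, members ordered by descending length."""
    by_start: dict[tuple[str, int], dict[int, str]] = {}
    by_end: dict[tuple[str, int], dict[int, str]] = {}
    for rec in records:
        for acc, start, end in rec.matches:
            by_start.setdefault((acc, start), {})[end - start + 1] = rec.peptide_id
            by_end.setdefault((acc, end), {})[end - start + 1] = rec.peptide_id

    ladders = []
    for (acc, coord), members in sorted(by_start.items()):
        if len(members) >= min_rungs:
            lengths = sorted(members, reverse=True)
            ladders.append(
                Ladder(acc, "N", coord, [members[ln] for ln in lengths], lengths)
            )
    for (acc, coord), members in sorted(by_end.items()):
        if len(members) >= min_rungs:
            lengths = sorted(members, reverse=True)
            ladders.append(
                Ladder(acc, "C", coord, [members[ln] for ln in lengths], lengths)
            )
    return ladders


def ladder_table(ladders: list[Ladder]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [l.accession for l in ladders],
            "shared_terminus": [l.shared_terminus for l in ladders],
            "coordinate": [l.coordinate for l in ladders],
            "n_rungs": [len(l.members) for l in ladders],
            "members": [";".join(l.members) for l in ladders],
            "steps": [";".join(map(str, l.steps)) for l in ladders],
        }
    )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def coverage_map(
    records: list[PeptideRecord], db: ProteinDB, accession: str
) -> np.ndarray:
    """Per-residue count of peptides covering each position of a protein."""
    if accession not in db:
        raise KeyError(f"unknown accession {accession!r}")
    cov = np.zeros(len(db[accession]), dtype=int)
    for rec in records:
        for acc, start, end in rec.matches:
            if acc == accession:
                cov[start - 1 : end] += 1
    return cov


# ---------------------------------------------------------------------------
# Group uniqueness / Venn partition
# ---------------------------------------------------------------------------

@dataclass
class UniquenessReport:
    """Per-cyst-type detection and uniqueness counts plus the full Venn
    partition over groups (feature is detected in a group iff present in at
    least one of its samples)."""

    detected: dict[str, int]
    unique: dict[str, int]
    shared_all: int
    venn: dict[frozenset, int]
    detected_proteins: dict[str, int] | None = None
    unique_proteins: dict[str, int] | None = None
    shared_all_proteins: int | None = None

    def table(self) -> pd.DataFrame:
        rows = []
        for g in self.detected:
            rows.append(
                {
                    "group": g,
                    "detected_features": self.detected[g],
                    "unique_features": self.unique[g],
                    "detected_proteins": (self.detected_proteins or {}).get(g),
                    "unique_proteins": (self.unique_proteins or {}).get(g),
                }
            )
        rows.append(
            {
                "group": "shared_in_all",
                "detected_features": self.shared_all,
                "unique_features": np.nan,
                "detected_proteins": self.shared_all_proteins,
                "unique_proteins": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _partition(sets: dict[str, set[str]]) -> dict[frozenset, int]:
    membership: dict[str, set[str]] = {}
    for g, feats in sets.items():
        for f in feats:
            membership.setdefault(f, set()).add(g)
    part: dict[frozenset, int] = {}
    for f, gs in membership.items():
        part[frozenset(gs)] = part.get(frozenset(gs), 0) + 1
    return part


def group_uniqueness(
    m: QuantMatrix,
    samples: pd.DataFrame,
    feature_to_protein: dict[str, str] | None = None,
    exclude_groups: tuple[str, ...] = ("UNC",),
) -> UniquenessReport:
    """Detection/uniqueness census across cyst types.

    A feature counts as detected in a group iff non-missing in >= 1 of the
    group's samples; unique = detected in exactly one group; shared-in-all =
    detected in every group. With a feature -> protein map the same census is
    reported at protein level.
    """
    groups = samples["group"].reindex(m.sample_ids)
    labels = [g for g in pd.unique(groups.dropna()) if g not in exclude_groups]
    det_sets: dict[str, set[str]] = {}
    present = m.data.notna()
    for g in labels:
        cols = groups[groups == g].index
        det = present[cols].any(axis=1)
        det_sets[g] = set(det.index[det])

    part = _partition(det_sets)
    unique = {
        g: sum(c for gs, c in part.items() if gs == frozenset([g])) for g in labels
    }
    shared_all = part.get(frozenset(labels), 0)
    rep = UniquenessReport(
        detected={g: len(det_sets[g]) for g in labels},
        unique=unique,
        shared_all=shared_all,
        venn=part,
    )
    if feature_to_protein is not None:
        prot_sets = {
            g: {feature_to_protein[f] for f in feats if f in feature_to_protein}
            for g, feats in det_sets.items()
        }
        ppart = _partition(prot_sets)
        rep.detected_proteins = {g: len(prot_sets[g]) for g in labels}
        rep.unique_proteins = {
            g: sum(c for gs, c in ppart.items() if gs == frozenset([g])) for g in labels
        }
        rep.shared_all_proteins = ppart.get(frozenset(labels), 0)
    return rep
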