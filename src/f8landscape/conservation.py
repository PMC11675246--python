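"""Per-position evolutionary conservation from an aligned ortholog set.

The conservation score of a reference position is the fraction of retained
ortholog species whose aligned residue equals the human reference residue:
1.0 means every species carries the human residue. Species with long
contiguous stretches of missing sequence (gap runs) opposite the reference
are removed before scoring, because such fragments say nothing about
per-residue substitution tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import EmptyInputError, MissingReferenceError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")


@dataclass
class AlignmentMatrix:
    """An aligned protein set as an (n_species, n_columns) character matrix.

    Rows are uppercase residue/gap characters; ``ref_species_id`` names the
    row that defines reference numbering (human F8-202 in the motivating
    analysis).
    """

    species_ids: list[str]
    rows: np.ndarray  # dtype '<U1', shape (n_species, n_columns)
    ref_species_id: str

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype="U1")
        if self.rows.ndim != 2:
            raise ValueError("rows must be a 2-D character matrix")
        if len(self.species_ids) != self.rows.shape[0]:
            raise ValueError("species_ids length must match number of rows")
        if self.ref_species_id not in self.species_ids:
            raise MissingReferenceError(self.ref_species_id)
        # case-insensitive residue comparison downstream
        self.rows = np.char.upper(self.rows)

    @property
    def n_species(self) -> int:
        return self.rows.shape[0]

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    @property
    def ref_row(self) -> np.ndarray:
        return self.rows[self.species_ids.index(self.ref_species_id)]

    @classmethod
    def from_fasta(cls, path, ref_species_id: str) -> "AlignmentMatrix":
        """Read an aligned FASTA file (all records equal length)."""
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(list(str(rec.seq).upper()))
        if not ids:
            raise EmptyInputError(f"no sequences in {path}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("unequal row lengths: input is not an alignment")
        return cls(ids, np.array(rows, dtype="U1"), ref_species_id)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.species_ids, self.rows):
                fh.write(f">{sid}\n{''.join(row)}\n")


@dataclass
class ConservationProfile:
    """Conservation score and residue counts for every ungapped reference position.

    ``scores[p-1]`` is the fraction (in [0, 1]) of retained species matching the
    reference residue at 1-based reference position ``p``. ``residue_counts``
    maps each position to an amino-acid frequency table over retained species;
    gap and X characters count toward the denominator but never match.
    """

    ref_positions: np.ndarray          # 1..L
    ref_residues: np.ndarray           # '<U1'
    scores: np.ndarray                 # float in [0,1]
    residue_counts: list[dict[str, int]]
    n_species_retained: int

    def score_at(self, position: int) -> float:
        """Score at a 1-based reference position."""
        idx = position - 1
        if idx < 0 or idx >= len(self.scores):
            raise KeyError(f"position {position} outside reference 1..{len(self.scores)}")
        return float(self.scores[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.ref_positions,
                "ref_residue": self.ref_residues,
                "score": self.scores,
                "n_species_retained": self.n_species_retained,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ConservationProfile":
        df = pd.read_csv(path, sep="\t")
        n_ret = int(df["n_species_retained"].iloc[0]) if len(df) else 0
        counts = [{} for _ in range(len(df))]
        return cls(
            ref_positions=df["position"].to_numpy(),
            ref_residues=df["ref_residue"].to_numpy(dtype="U1"),
            scores=df["score"].to_numpy(dtype=float),
            residue_counts=counts,
            n_species_retained=n_ret,
        )


def _is_gap(chars: np.ndarray) -> np.ndarray:
    out = np.zeros(chars.shape, dtype=bool)
    for g in GAP_CHARS:
        out |= chars == g
    return out


def _max_gap_run(mask: np.ndarray) -> int:
    """Longest run of True in a boolean vector."""
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def filter_species(aln: AlignmentMatrix, max_gap_run: int = 10) -> AlignmentMatrix:
    """Drop species with a contiguous missing region longer than ``max_gap_run``.

    Gap runs are measured over the columns where the reference itself is
    non-gap, so insertions private to other species do not count as missing
    reference coverage. A run of exactly ``max_gap_run`` is retained; the
    reference row is always retained.
    """
    ref_nongap = ~_is_gap(aln.ref_row)
    keep = []
    for i, sid in enumerate(aln.species_ids):
        if sid == aln.ref_species_id:
            keep.append(i)
            continue
        gaps = _is_gap(aln.rows[i])[ref_nongap]
        if _max_gap_run(gaps) <= max_gap_run:
            keep.append(i)
    return AlignmentMatrix(
        [aln.species_ids[i] for i in keep], aln.rows[keep], aln.ref_species_id
    )


def map_columns_to_ref(aln: AlignmentMatrix) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based ungapped reference positions.

    Columns where the reference is a gap are absent from the map.
    """
    ref_nongap = ~_is_gap(aln.ref_row)
    cols = np.flatnonzero(ref_nongap) + 1
    return {int(c): p for p, c in enumerate(cols, start=1)}


def conservation(aln: AlignmentMatrix, exclude_gaps: bool = False) -> ConservationProfile:
    """Compute the per-reference-position conservation profile.

    With the default ``exclude_gaps=False`` every retained species counts in
    the denominator, so gaps and X dilute the score; with ``exclude_gaps=True``
    only species with a residue character at the column are counted.
    """
    if aln.n_species == 0 or aln.n_columns == 0:
        raise EmptyInputError("empty alignment")
    ref = aln.ref_row
    ref_nongap = ~_is_gap(ref)
    cols = np.flatnonzero(ref_nongap)
    sub = aln.rows[:, cols]                       # (n_species, L)
    ref_res = ref[cols]
    matches = (sub == ref_res[None, :]).sum(axis=0)
    if exclude_gaps:
        informative = (~_is_gap(sub) & (sub != "X")).sum(axis=0)
        denom = np.maximum(informative, 1)
        scores = matches / denom
        n_ret = aln.n_species
    else:
        n_ret = aln.n_species
        scores = matches / n_ret

    counts: list[dict[str, int]] = []
    for j in range(sub.shape[1]):
        vals, cnts = np.unique(sub[:, j], return_counts=True)
        counts.append({str(v): int(c) for v, c in zip(vals, cnts)})

    L = len(cols)
    return ConservationProfile(
        ref_positions=np.arange(1, L + 1),
        ref_residues=ref_res.copy(),
        scores=scores.astype(float),
        residue_counts=counts,
        n_species_retained=n_ret,
    )
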