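"""Cα-trajectory analysis: RMSD, RMSF, cross-correlation, and spatial clusters.

Per-residue motion is reduced to Cα coordinates over trajectory frames. After
rigid-body superposition removes global translation/rotation, the dynamics
cross-correlation (DCC) between residues i and j is the normalized covariance
of their displacement vectors,

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>),   dr_i(t) = r_i(t) - <r_i>,

which lies in [-1, 1]: 1 for lock-step motion, -1 for anti-correlated motion.
Residues carrying variants of uncertain significance are summarized by how
many known-pathogenic residues (and how many residues of a binding partner
chain, here VWF) they correlate with above given thresholds, and the top
uncertain residues are grouped into spatial clusters by single-linkage on
Cα distance in the reference structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .errors import BookkeepingError, DegenerateStructureError, LabelError

ResidueLabel = tuple[str, int, str]  # (chain_id, residue_number, aa three-letter)


@dataclass
class Trajectory:
    """Cα coordinates over frames: ``coords`` has shape (n_frames, n_residues, 3) in Å."""

    coords: np.ndarray
    labels: list[ResidueLabel]
    interval_ps: float = 100.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_residues, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("labels must match residue count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def mean_structure(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    # -- I/O ---------------------------------------------------------------

    def to_pdb(self, path) -> None:
        """Write as a multi-model Cα-only PDB (MODEL/ATOM/ENDMDL records)."""
        with open(path, "w") as fh:
            for m, frame in enumerate(self.coords, start=1):
                fh.write(f"MODEL     {m:4d}\n")
                for a, ((chain, resnum, aa), xyz) in enumerate(zip(self.labels, frame), 1):
                    fh.write(
                        f"ATOM  {a:5d}  CA  {aa:<3s} {chain}{resnum:4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")

    @classmethod
    def from_pdb(cls, path, interval_ps: float = 100.0) -> "Trajectory":
        """Read a multi-model Cα PDB written by :meth:`to_pdb` (or equivalent)."""
        frames: list[list[tuple[float, float, float]]] = []
        labels: list[ResidueLabel] = []
        current: list[tuple[float, float, float]] | None = None
        first = True
        with open(path) as fh:
            for line in fh:
                if line.startswith("MODEL"):
                    current = []
                elif line.startswith("ENDMDL"):
                    frames.append(current or [])
                    first = False
                    current = None
                elif line.startswith("ATOM") and line[12:16].strip() == "CA":
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                    if current is None:  # single-model file without MODEL records
                        current = []
                        frames.append(current)
                    current.append(xyz)
                    if first:
                        labels.append(
                            (line[21].strip() or "A", int(line[22:26]), line[17:20].strip())
                        )
        coords = np.array(frames, dtype=float)
        return cls(coords=coords, labels=labels, interval_ps=interval_ps)

    def to_tsv(self, path) -> None:
        """Write a plain per-frame coordinate table (frame, chain, resnum, aa, x, y, z)."""
        rows = []
        for t, frame in enumerate(self.coords):
            for (chain, resnum, aa), xyz in zip(self.labels, frame):
                rows.append((t, chain, resnum, aa, *xyz))
        pd.DataFrame(
            rows, columns=["frame", "chain", "resnum", "aa", "x", "y", "z"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, interval_ps: float = 100.0) -> "Trajectory":
        df = pd.read_csv(path, sep="\t")
        frames = sorted(df["frame"].unique())
        f0 = df[df["frame"] == frames[0]]
        labels = [(str(c), int(r), str(a)) for c, r, a in zip(f0["chain"], f0["resnum"], f0["aa"])]
        coords = np.stack(
            [df[df["frame"] == t][["x", "y", "z"]].to_numpy(dtype=float) for t in frames]
        )
        return cls(coords=coords, labels=labels, interval_ps=interval_ps)


@dataclass
class DCCMatrix:
    """Symmetric residue-by-residue motion-correlation matrix with labels.

    ``undefined`` flags residues with zero fluctuation, whose rows/columns
    are NaN rather than silently zero.
    """

    values: np.ndarray
    labels: list[ResidueLabel]
    undefined: np.ndarray = field(default=None)  # bool per residue

    def __post_init__(self):
        if self.undefined is None:
            self.undefined = np.zeros(len(self.labels), dtype=bool)

    def index_of(self, chain: str, resnum: int) -> int:
        for i, (c, r, _aa) in enumerate(self.labels):
            if c == chain and r == resnum:
                return i
        raise LabelError(f"residue {chain}/{resnum} not in matrix")

    def to_tsv(self, path) -> None:
        names = [f"{c}{r}" for c, r, _ in self.labels]
        pd.DataFrame(self.values, index=names, columns=names).to_csv(path, sep="\t")


def expected_frames(total_ns: float, interval_ps: float) -> int:
    """Snapshot count for a run of ``total_ns`` sampled every ``interval_ps``.

    The frame at t=0 is included, so 80 ns at 100 ps yields 801.
    """
    total_ps = total_ns * 1000.0
    n, rem = divmod(total_ps, interval_ps)
    if abs(rem) > 1e-9 * max(1.0, total_ps):
        raise BookkeepingError(
            f"interval {interval_ps} ps does not divide {total_ns} ns evenly"
        )
    return int(round(n)) + 1


def _kabsch_align(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body alignment of one frame onto a target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(target - tc, mobile - mc)
    return (mobile - mc) @ rot.as_matrix().T + tc


def _kabsch_align_batch(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Kabsch alignment of every frame onto a target, batched over frames.

    Proper rotations only: the reflection case is handled through the sign of
    det(V U^T), as in the standard Kabsch construction.
    """
    tc = target.mean(axis=0)
    Q = target - tc                                   # (N, 3)
    mc = coords.mean(axis=1, keepdims=True)           # (T, 1, 3)
    P = coords - mc                                   # (T, N, 3)
    H = np.einsum("tna,nb->tab", P, Q)                # covariance per frame
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("tab,tcb->tac", Vt, U)))
    D = np.repeat(np.eye(3)[None], len(coords), axis=0)
    D[:, 2, 2] = d
    R = np.einsum("tba,tbc,tdc->tad", Vt, D, U)       # V @ D @ U^T, (T,3,3)
    return np.einsum("tna,tba->tnb", P, R) + tc


def superpose(traj: Trajectory, reference: np.ndarray | None = None) -> Trajectory:
    """Remove global rigid-body motion from every frame.

    With no explicit reference, a two-pass scheme is used: frames are first
    aligned to frame 0, then re-aligned to the mean structure of that pass,
    which removes the arbitrary choice of first frame as orientation anchor.
    """
    if traj.n_residues < 3:
        raise DegenerateStructureError("need >= 3 residues for superposition")
    spread = traj.coords[0] - traj.coords[0].mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-8) < 2:
        raise DegenerateStructureError("collinear coordinates: rotation ill-defined")

    if reference is not None:
        aligned = _kabsch_align_batch(traj.coords, np.asarray(reference, dtype=float))
    else:
        pass1 = _kabsch_align_batch(traj.coords, traj.coords[0])
        aligned = _kabsch_align_batch(pass1, pass1.mean(axis=0))
    return Trajectory(coords=aligned, labels=list(traj.labels), interval_ps=traj.interval_ps)


def rmsd_series(traj: Trajectory, reference: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD (Å) against a reference (default: mean structure)."""
    ref = traj.mean_structure() if reference is None else np.asarray(reference, dtype=float)
    d = traj.coords - ref[None, :, :]
    return np.sqrt((d ** 2).sum(axis=2).mean(axis=1))


def rmsf_per_residue(traj: Trajectory) -> np.ndarray:
    """Per-residue root-mean-square fluctuation (Å) about the time-mean position."""
    d = traj.coords - traj.mean_structure()[None, :, :]
    return np.sqrt((d ** 2).sum(axis=2).mean(axis=0))


def dcc(traj: Trajectory) -> DCCMatrix:
    """Dynamics cross-correlation matrix over residue displacement vectors.

    Vectorized over frames; residues with zero fluctuation get NaN
    rows/columns and are flagged in ``undefined``.
    """
    X = traj.coords - traj.mean_structure()[None, :, :]   # (T, N, 3)
    T = X.shape[0]
    cov = np.einsum("tia,tja->ij", X, X) / T
    var = np.diag(cov).copy()
    undefined = var <= 0
    denom = np.sqrt(np.where(undefined, np.nan, var))
    C = cov / denom[:, None] / denom[None, :]
    np.fill_diagonal(C, np.where(undefined, np.nan, 1.0))
    C = np.clip(C, -1.0, 1.0)
    return DCCMatrix(values=C, labels=list(traj.labels), undefined=undefined)


@dataclass
class CorrelationSummary:
    """How strongly one uncertain residue co-moves with pathogenic/partner residues."""

    vus: ResidueLabel
    pathogenic_counts: dict[float, int]
    partner_counts: dict[float, int]
    top_pathogenic: list[tuple[ResidueLabel, float]]
    top_partner: list[tuple[ResidueLabel, float]]


def correlation_summary(
    matrix: DCCMatrix,
    vus_residues: list[tuple[str, int]],
    pathogenic_residues: list[tuple[str, int]],
    partner_chain: str | None = None,
    thresholds: tuple[float, ...] = (0.8, 0.85, 0.9),
) -> list[CorrelationSummary]:
    """Count, per uncertain residue, correlated pathogenic and partner residues.

    For each residue in ``vus_residues`` and each threshold, counts the
    pathogenic residues (excluding the residue itself) with C >= threshold,
    and likewise the residues of ``partner_chain`` (the binding partner, e.g.
    the VWF chain). Partner lists are sorted by correlation descending.
    """
    thresholds = tuple(sorted(thresholds))
    path_idx = [matrix.index_of(c, r) for c, r in pathogenic_residues]
    if partner_chain is not None:
        part_idx = [i for i, (c, _r, _aa) in enumerate(matrix.labels) if c == partner_chain]
    else:
        part_idx = []

    out = []
    for chain, resnum in vus_residues:
        i = matrix.index_of(chain, resnum)
        row = matrix.values[i]

        def _summarize(idxs):
            idxs = [j for j in idxs if j != i]
            vals = [(matrix.labels[j], float(row[j])) for j in idxs if np.isfinite(row[j])]
            vals.sort(key=lambda t: (-t[1], t[0][0], t[0][1]))
            counts = {th: sum(1 for _l, v in vals if v >= th) for th in thresholds}
            return counts, vals

        p_counts, p_vals = _summarize(path_idx)
        w_counts, w_vals = _summarize(part_idx)
        out.append(
            CorrelationSummary(
                vus=matrix.labels[i],
                pathogenic_counts=p_counts,
                partner_counts=w_counts,
                top_pathogenic=p_vals[:25],
                top_partner=w_vals[:25],
            )
        )
    return out


def summary_frame(summaries: list[CorrelationSummary]) -> pd.DataFrame:
    """Tabulate correlation summaries (one row per VUS residue and threshold)."""
    rows = []
    for s in summaries:
        for th in s.pathogenic_counts:
            rows.append(
                {
                    "chain": s.vus[0], "resnum": s.vus[1], "threshold": th,
                    "n_pathogenic": s.pathogenic_counts[th],
                    "n_partner": s.partner_counts.get(th, 0),
                }
            )
    return pd.DataFrame(rows)


def cluster_top_vus(
    coords_by_residue: dict[tuple[str, int], np.ndarray],
    top_vus_residues: list[tuple[str, int]],
    cutoff_angstrom: float = 12.0,
) -> dict[tuple[str, int], int]:
    """Group top uncertain residues into spatial clusters.

    Single-linkage connected components under Euclidean Cα distance
    <= ``cutoff_angstrom`` in the reference structure. Cluster ids are
    1-based, numbered by first residue appearance.
    """
    missing = [r for r in top_vus_residues if r not in coords_by_residue]
    if missing:
        raise LabelError(f"no coordinates for residues: {missing}")
    if not top_vus_residues:
        return {}
    if len(top_vus_residues) == 1:
        return {top_vus_residues[0]: 1}
    pts = np.array([coords_by_residue[r] for r in top_vus_residues], dtype=float)
    Z = linkage(pdist(pts), method="single")
    raw = fcluster(Z, t=cutoff_angstrom, criterion="distance")
    # renumber clusters in order of first appearance
    remap: dict[int, int] = {}
    assignment = {}
    for res, c in zip(top_vus_residues, raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        assignment[res] = remap[c]
    return assignment
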