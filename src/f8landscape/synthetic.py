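"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one input class of the variant-landscape analysis —
an ortholog alignment with controlled per-column conservation, multi-source
variant tables with controlled overlap and zygosity, prediction-tool score
panels with separable pathogenic/VUS distributions, block-correlated Cα
trajectories, and an eQTL summary table with one embedded co-inherited
block — so that every downstream statistic can be checked against the value
it was constructed to have. All generators are deterministic given a seed.

None of this is a biophysical simulation: the trajectory model is
block-correlated Gaussian displacement about fixed mean positions, which is
sufficient because the dynamics cross-correlation is a pure second-moment
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import AA20, AlignmentMatrix, ConservationProfile
from .errors import InvalidSpecError
from .scoring import TOOL_NORMALIZATIONS, denormalize_tool

REF_ID = "Homo_sapiens_F8"

GNOMAD_POPULATIONS = (
    "African/African American",
    "Admixed American",
    "East Asian",
    "European",
    "Middle Eastern",
    "South Asian",
    "Remaining",
)


# ---------------------------------------------------------------------------
# Multiple-sequence alignment
# ---------------------------------------------------------------------------

@dataclass
class MsaSpec:
    """Recipe for an aligned ortholog set with known per-column conservation.

    ``conservation_targets[p]`` is the fraction of non-corrupted species that
    carry the reference residue at position ``p+1``. ``long_gap_species``
    species are corrupted with one contiguous gap of ``gap_length`` columns,
    emulating fragmented database sequences that the species filter removes.
    """

    n_species: int
    ref_length: int
    conservation_targets: np.ndarray
    long_gap_species: int = 0
    gap_length: int = 11
    seed: int = 0

    def __post_init__(self):
        self.conservation_targets = np.asarray(self.conservation_targets, dtype=float)
        if self.n_species < 2:
            raise InvalidSpecError("n_species must be >= 2")
        if self.gap_length < 1:
            raise InvalidSpecError("gap_length must be >= 1")
        if self.long_gap_species > 0 and self.gap_length > self.ref_length:
            raise InvalidSpecError("gap_length exceeds reference length")
        if len(self.conservation_targets) != self.ref_length:
            raise InvalidSpecError("conservation_targets must cover the reference")
        if ((self.conservation_targets < 0) | (self.conservation_targets > 1)).any():
            raise InvalidSpecError("conservation targets must lie in [0,1]")
        if self.long_gap_species >= self.n_species:
            raise InvalidSpecError("cannot corrupt every species")


def make_msa(spec: MsaSpec) -> tuple[AlignmentMatrix, np.ndarray]:
    """Generate an alignment whose conservation profile is known by construction.

    Returns the alignment and the realized conservation vector over
    non-corrupted species (within 1/n of the requested targets, n the count
    of non-corrupted species). Mismatching species draw uniformly from the 19
    non-reference amino acids. Corrupted species are the last
    ``long_gap_species`` rows.
    """
    rng = np.random.default_rng(spec.seed)
    L, n = spec.ref_length, spec.n_species
    n_clean = n - spec.long_gap_species

    ref = rng.choice(list(AA20), size=L)
    rows = np.tile(ref, (n, 1))

    realized = np.empty(L)
    for p in range(L):
        n_match = int(round(spec.conservation_targets[p] * n_clean))
        n_match = max(1, n_match)  # the reference always matches itself
        realized[p] = n_match / n_clean
        mism = rng.choice(np.arange(1, n_clean), size=n_clean - n_match, replace=False)
        alts = [a for a in AA20 if a != ref[p]]
        rows[mism, p] = rng.choice(alts, size=len(mism))

    # corrupt the tail species with one contiguous gap each
    for i in range(n_clean, n):
        start = int(rng.integers(0, L - spec.gap_length + 1))
        rows[i, start : start + spec.gap_length] = "-"

    ids = [REF_ID] + [f"species_{i:04d}" for i in range(1, n)]
    return AlignmentMatrix(ids, rows, REF_ID), realized


# ---------------------------------------------------------------------------
# Cα trajectory
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Recipe for a block-correlated Gaussian Cα trajectory.

    Each entry of ``correlation_blocks`` is ``(residue_indices, rho)``: the
    listed residues share a latent displacement factor so their pairwise
    vector-displacement correlation equals ``rho``. For ``rho < 0`` the first
    residue of the block moves against the rest (all-pairs negative
    correlation is impossible for blocks larger than two). ``noise_sd`` adds
    independent jitter (Å) on top of the unit-amplitude correlated motion.
    """

    n_frames: int
    n_residues: int
    correlation_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    noise_sd: float = 0.0
    interval_ps: float = 100.0
    chain_id: str = "A"
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise InvalidSpecError("n_frames must be >= 2")
        seen: set[int] = set()
        for idx, rho in self.correlation_blocks:
            if abs(rho) > 1:
                raise InvalidSpecError("|target correlation| must be <= 1")
            s = set(idx)
            if s & seen:
                raise InvalidSpecError("correlation blocks must be disjoint")
            if max(s, default=-1) >= self.n_residues or min(s, default=0) < 0:
                raise InvalidSpecError("block residue index out of range")
            seen |= s


def make_trajectory(spec: TrajectorySpec):
    """Generate a trajectory realizing the requested block-correlation structure.

    Displacement of residue i at frame t is
    ``s_i sqrt(|rho|) g_b(t) + sqrt(1-|rho|) e_i(t) + noise_sd * h_i(t)``
    with g, e, h independent standard 3-D Gaussians, g shared within the
    block, and s_i = -1 for non-leader members of a negative block. Residues
    outside every block move independently. Mean positions are spread on a
    coarse 3-D grid so residues are spatially distinguishable.
    """
    from .dynamics import Trajectory  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    T, N = spec.n_frames, spec.n_residues

    # mean positions: points on a jittered grid, ~10 A spacing
    side = int(np.ceil(N ** (1 / 3)))
    grid = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )[:N] * 10.0
    means = grid + rng.normal(scale=0.5, size=(N, 3))

    disp = rng.standard_normal((T, N, 3))  # independent part, unit SD
    for idx, rho in spec.correlation_blocks:
        g = rng.standard_normal((T, 1, 3))
        a = np.sqrt(abs(rho))
        b = np.sqrt(1.0 - abs(rho))
        signs = np.ones(len(idx))
        if rho < 0:
            signs[1:] = -1.0
        disp[:, idx, :] = signs[None, :, None] * a * g + b * disp[:, idx, :]
    if spec.noise_sd > 0:
        disp = disp + spec.noise_sd * rng.standard_normal((T, N, 3))

    coords = means[None, :, :] + disp
    labels = [(spec.chain_id, i + 1, "ALA") for i in range(N)]
    return Trajectory(coords=coords, labels=labels, interval_ps=spec.interval_ps)


# ---------------------------------------------------------------------------
# Variant tables and tool-score panels
# ---------------------------------------------------------------------------

SOURCE_GROUPS = ("UniProt", "ClinVar_Path", "ClinVar_VUS", "Geno2MP", "gnomAD")


@dataclass
class VariantTableSpec:
    """Recipe for multi-source missense-variant tables plus a tool-score panel.

    ``counts`` gives the number of variants whose primary source is each
    group. ``gnomad_overlap`` is the probability that a non-gnomAD-primary
    variant also appears in gnomAD (and thus carries allele-frequency and
    zygosity fields); ``cross_overlap`` the probability it is co-listed in one
    additional evidence source. ``vus_pathogenic_fraction`` of the
    ClinVar-VUS/Geno2MP variants are flagged ground-truth pathogenic and draw
    their tool scores from the pathogenic distribution. ``separation_sd`` is
    the pathogenic-vs-VUS mean separation in pooled-SD units on the
    normalized score scale.
    """

    counts: dict[str, int] = field(
        default_factory=lambda: {
            "UniProt": 40, "ClinVar_Path": 120, "ClinVar_VUS": 200,
            "Geno2MP": 120, "gnomAD": 300,
        }
    )
    gnomad_overlap: float = 0.5
    cross_overlap: float = 0.15
    vus_pathogenic_fraction: float = 0.1
    separation_sd: float = 3.0
    score_sd: float = 0.08
    af_log10_mean: float = -4.0
    af_log10_sd: float = 1.0
    hemizygote_rate: float = 0.8
    homozygote_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for g, c in self.counts.items():
            if g not in SOURCE_GROUPS:
                raise InvalidSpecError(f"unknown source group {g!r}")
            if c < 0:
                raise InvalidSpecError("counts must be >= 0")
        for frac in (self.gnomad_overlap, self.cross_overlap, self.vus_pathogenic_fraction):
            if not 0 <= frac <= 1:
                raise InvalidSpecError("overlap fractions must lie in [0,1]")


def make_variant_tables(
    spec: VariantTableSpec, profile: ConservationProfile
) -> dict[str, pd.DataFrame]:
    """Generate per-source variant tables, a tool-score panel, and ground truth.

    Returns a dict with one DataFrame per source group (keys as in
    ``SOURCE_GROUPS``), a ``panel`` DataFrame of raw prediction-tool scores,
    and a ``truth`` DataFrame flagging which variants were drawn pathogenic.
    Positions are sampled without replacement from the conservation profile,
    so each amino-acid change is unique.
    """
    rng = np.random.default_rng(spec.seed)
    L = len(profile.scores)
    total = sum(spec.counts.values())
    if total == 0:
        empty_cols = ["variant", "ref_aa", "position", "alt_aa"]
        out = {g: pd.DataFrame(columns=empty_cols) for g in SOURCE_GROUPS}
        out["panel"] = pd.DataFrame(columns=["variant"] + list(TOOL_NORMALIZATIONS))
        out["truth"] = pd.DataFrame(columns=["variant", "truth_pathogenic"])
        return out
    if total > L:
        raise InvalidSpecError(
            f"{total} variants requested but the reference has only {L} positions"
        )

    positions = rng.choice(np.arange(1, L + 1), size=total, replace=False)
    records = []
    i = 0
    for group, count in spec.counts.items():
        for _ in range(count):
            pos = int(positions[i]); i += 1
            ref_aa = str(profile.ref_residues[pos - 1])
            alt_aa = str(rng.choice([a for a in AA20 if a != ref_aa]))
            is_path = group in ("UniProt", "ClinVar_Path")
            if group in ("ClinVar_VUS", "Geno2MP"):
                is_path = bool(rng.random() < spec.vus_pathogenic_fraction)
            groups = {group}
            if group != "gnomAD" and rng.random() < spec.gnomad_overlap:
                groups.add("gnomAD")
            if group != "gnomAD" and rng.random() < spec.cross_overlap:
                extra = rng.choice([g for g in ("UniProt", "ClinVar_VUS", "Geno2MP")
                                    if g != group])
                groups.add(str(extra))
            records.append(
                {
                    "variant": f"{ref_aa}{pos}{alt_aa}",
                    "ref_aa": ref_aa, "position": pos, "alt_aa": alt_aa,
                    "primary": group, "groups": groups, "truth_pathogenic": is_path,
                }
            )

    # gnomAD population frequencies + zygosity for every gnomAD-listed variant
    rows_by_source: dict[str, list[dict]] = {g: [] for g in SOURCE_GROUPS}
    panel_rows, truth_rows = [], []
    for rec in records:
        base = {"variant": rec["variant"], "ref_aa": rec["ref_aa"],
                "position": rec["position"], "alt_aa": rec["alt_aa"]}
        if "gnomAD" in rec["groups"]:
            afs = 10.0 ** rng.normal(spec.af_log10_mean, spec.af_log10_sd,
                                     size=len(GNOMAD_POPULATIONS))
            afs = np.clip(afs, 0.0, 0.5)
            hemi = int(rng.poisson(5)) if rng.random() < spec.hemizygote_rate else 0
            homo = int(rng.poisson(1)) if rng.random() < spec.homozygote_rate else 0
            gn = dict(base)
            for p, af in zip(GNOMAD_POPULATIONS, afs):
                gn[f"af_{p}"] = af
            gn["overall_af"] = float(afs.mean())
            gn["hemizygotes"] = hemi
            gn["homozygotes"] = homo
            rows_by_source["gnomAD"].append(gn)
        for g in rec["groups"] - {"gnomAD"}:
            row = dict(base)
            if g in ("ClinVar_Path", "ClinVar_VUS"):
                row["clinvar_class"] = (
                    "pathogenic" if g == "ClinVar_Path" else "VUS"
                )
            if g == "Geno2MP":
                row["geno2mp_homozygous"] = int(rng.random() < 0.1)
                row["phenotypes"] = "synthetic phenotype"
            rows_by_source[g].append(row)

        # tool scores on the normalized scale, then mapped to raw tool ranges
        center = 0.85 if rec["truth_pathogenic"] else 0.85 - spec.separation_sd * spec.score_sd
        panel = {"variant": rec["variant"]}
        for tool in TOOL_NORMALIZATIONS:
            norm = float(np.clip(rng.normal(center, spec.score_sd), 0.0, 1.0))
            panel[tool] = denormalize_tool(tool, norm)
        panel_rows.append(panel)
        truth_rows.append({"variant": rec["variant"],
                           "truth_pathogenic": rec["truth_pathogenic"],
                           "groups": ",".join(sorted(rec["groups"]))})

    out = {g: pd.DataFrame(rows_by_source[g]) for g in SOURCE_GROUPS}
    out["panel"] = pd.DataFrame(panel_rows)
    out["truth"] = pd.DataFrame(truth_rows)
    return out


# ---------------------------------------------------------------------------
# eQTL summary table
# ---------------------------------------------------------------------------

def make_eqtl_table(
    block_size: int,
    span: int = 50_058,
    n_background: int = 50,
    block_start: int = 155_001_128,
    tissue: str = "Nerve - Tibial",
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an eQTL summary table with one embedded co-inherited block.

    The block's ``block_size`` members share an effect size and -log10 p to
    within a tiny jitter and span exactly ``span`` bases; background variants
    scatter widely in both statistics so no tolerance-based grouping can
    absorb them.
    """
    if block_size < 1:
        raise InvalidSpecError("block_size must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    if block_size == 1:
        pos = np.array([block_start])
    else:
        inner = np.sort(rng.choice(np.arange(1, span), size=block_size - 2,
                                   replace=False)) if block_size > 2 else np.array([], int)
        pos = np.concatenate(([0], inner, [span])) + block_start
    eff = 0.45
    mlp = 12.0
    for k, p in enumerate(pos):
        rows.append({"rsid": f"rs_block_{k:03d}", "chrom": "chrX", "pos": int(p),
                     "minus_log10_p": mlp + rng.normal(0, 0.01),
                     "effect_size": eff + rng.normal(0, 0.002),
                     "tissue": tissue, "in_block": True})
    for k in range(n_background):
        p = int(rng.integers(block_start - 2_000_000, block_start + 2_000_000))
        # -log10 p spread on a coarse grid (and kept away from the block's
        # value) so that no two background records fall within any reasonable
        # pairwise tolerance
        bg_mlp = 0.5 + 0.8 * k
        if abs(bg_mlp - mlp) < 1.0:
            bg_mlp += 2.0
        rows.append({"rsid": f"rs_bg_{k:04d}", "chrom": "chrX", "pos": p,
                     "minus_log10_p": bg_mlp + float(rng.normal(0, 0.01)),
                     "effect_size": float((-1) ** k * (0.05 + 0.01 * k)),
                     "tissue": tissue, "in_block": False})
    df = pd.DataFrame(rows).sort_values("pos", kind="stable").reset_index(drop=True)
    return df
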