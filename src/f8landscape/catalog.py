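"""Harmonization of missense variants across evidence sources.

Variants from UniProt disease annotations, ClinVar (split into
pathogenic/likely-pathogenic and uncertain), Geno2MP, and gnomAD are merged
into one catalog keyed by the protein-level amino-acid change (e.g. E340K).
gnomAD rows contribute population allele frequencies and zygosity counts —
on the X chromosome, hemizygous male carriers and homozygous females are
the observations that speak to phenotype expression, so they are tracked
per variant. Filters then select changes at evolutionarily conserved
positions that nevertheless segregate at appreciable population frequency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservationProfile
from .errors import ConflictError, CoverageError

VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")

#: canonical evidence-source names
SOURCES = ("UniProt", "ClinVar_Path", "ClinVar_VUS", "Geno2MP", "gnomAD")


def parse_variant(label: str) -> tuple[str, int, str]:
    """Parse a protein change label like ``E340K`` into (ref, position, alt)."""
    m = VARIANT_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse variant label {label!r}")
    return m.group(1), int(m.group(2)), m.group(3)


@dataclass
class DomainAnnotation:
    """A named F8 region (signal peptide or A1/A2/B/A3/C1/C2 domain)."""

    name: str
    start: int
    end: int

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def merge_sources(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-source variant tables into one harmonized catalog.

    ``tables`` maps source names (see :data:`SOURCES`) to DataFrames that
    carry at least a ``variant`` column (or the ``ref_aa``/``position``/
    ``alt_aa`` triple). One catalog row is produced per unique amino-acid
    change; ``source_groups`` is the comma-joined union of sources listing
    it. Allele-frequency and zygosity fields are taken from gnomAD rows only.
    Two sources disagreeing on the reference residue at a position raise
    :class:`ConflictError`.
    """
    merged: dict[str, dict] = {}
    ref_at_pos: dict[int, tuple[str, str]] = {}  # position -> (ref_aa, first variant)

    for source, df in tables.items():
        if source not in SOURCES:
            raise ValueError(f"unknown source {source!r}")
        if df is None or len(df) == 0:
            continue
        for _, row in df.iterrows():
            if "variant" in row and isinstance(row["variant"], str):
                ref, pos, alt = parse_variant(row["variant"])
            else:
                ref, pos, alt = str(row["ref_aa"]), int(row["position"]), str(row["alt_aa"])
            key = f"{ref}{pos}{alt}"
            if pos in ref_at_pos and ref_at_pos[pos][0] != ref:
                raise ConflictError(
                    f"reference residue conflict at position {pos}: "
                    f"{ref_at_pos[pos][0]} (from {ref_at_pos[pos][1]}) vs {ref} (from {key})"
                )
            ref_at_pos.setdefault(pos, (ref, key))
            rec = merged.setdefault(
                key,
                {
                    "variant": key, "ref_aa": ref, "position": pos, "alt_aa": alt,
                    "source_groups": set(), "clinvar_class": None,
                    "overall_af": np.nan, "max_af": np.nan, "max_af_population": None,
                    "homozygote_count": 0, "hemizygote_count": 0,
                    "geno2mp_homozygous": 0, "phenotypes": [],
                },
            )
            rec["source_groups"].add(source)
            if source == "ClinVar_Path":
                rec["clinvar_class"] = str(row.get("clinvar_class") or "pathogenic")
            elif source == "ClinVar_VUS" and rec["clinvar_class"] is None:
                rec["clinvar_class"] = "VUS"
            if source == "gnomAD":
                af_cols = {c[3:]: float(row[c]) for c in df.columns if c.startswith("af_")}
                if af_cols:
                    pops, afs = list(af_cols), np.array(list(af_cols.values()))
                    imax = int(np.nanargmax(afs))
                    rec["max_af"] = float(afs[imax])
                    rec["max_af_population"] = pops[imax]
                    for p, a in af_cols.items():
                        rec[f"af_{p}"] = a
                if "overall_af" in row:
                    rec["overall_af"] = float(row["overall_af"])
                rec["homozygote_count"] = int(row.get("homozygotes", 0) or 0)
                rec["hemizygote_count"] = int(row.get("hemizygotes", 0) or 0)
            if source == "Geno2MP":
                rec["geno2mp_homozygous"] = int(row.get("geno2mp_homozygous", 0) or 0)
            ph = row.get("phenotypes")
            if isinstance(ph, str) and ph and ph != "-":
                if ph not in rec["phenotypes"]:
                    rec["phenotypes"].append(ph)

    if not merged:
        return _empty_catalog()
    df = pd.DataFrame(list(merged.values()))
    df["source_groups"] = df["source_groups"].map(lambda s: ",".join(sorted(s)))
    df["phenotypes"] = df["phenotypes"].map("; ".join)
    return df.sort_values("position", kind="stable").reset_index(drop=True)


def _empty_catalog() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "variant", "ref_aa", "position", "alt_aa", "source_groups",
            "clinvar_class", "overall_af", "max_af", "max_af_population",
            "homozygote_count", "hemizygote_count", "geno2mp_homozygous", "phenotypes",
        ]
    )


def groups_of(row) -> set[str]:
    """Source-group set of one catalog row (column is comma-joined)."""
    v = row["source_groups"] if not isinstance(row, str) else row
    if isinstance(v, str):
        return {g for g in v.split(",") if g}
    return set(v)


def annotate_conservation(catalog: pd.DataFrame, profile: ConservationProfile) -> pd.DataFrame:
    """Attach the per-position conservation score to every catalog record."""
    out = catalog.copy()
    L = len(profile.scores)
    bad = out.loc[(out["position"] < 1) | (out["position"] > L), "variant"].tolist()
    if bad:
        raise CoverageError(f"positions outside conservation profile: {bad}")
    out["conservation"] = [profile.score_at(int(p)) for p in out["position"]]
    return out


def filter_conserved_common(
    catalog: pd.DataFrame,
    min_conservation: float = 0.7,
    min_max_af: float = 0.001,
) -> pd.DataFrame:
    """Select conserved-yet-common variants backed by phenotype evidence.

    Keeps records with conservation strictly above ``min_conservation``, a
    maximum population allele frequency strictly above ``min_max_af``, and at
    least one evidence source besides gnomAD. Both thresholds are strict
    inequalities.
    """
    if "conservation" not in catalog.columns:
        raise CoverageError("catalog must be annotated with conservation first")
    evidence = {"UniProt", "ClinVar_Path", "ClinVar_VUS", "Geno2MP"}
    has_ev = catalog.apply(lambda r: bool(groups_of(r) & evidence), axis=1) \
        if len(catalog) else pd.Series(dtype=bool)
    mask = (
        (catalog["conservation"] > min_conservation)
        & (catalog["max_af"] > min_max_af)
        & has_ev
    )
    return catalog[mask].reset_index(drop=True)


def zygosity_summary(catalog: pd.DataFrame, group_filter: set[str] | None = None) -> pd.DataFrame:
    """Per-variant zygosity report with a hemizygous-only flag.

    ``hemizygous_only`` marks variants observed in hemizygous males but never
    in a homozygous female — the pattern under which female phenotype
    consequences are unobservable in population data.
    """
    df = catalog
    if group_filter:
        keep = df.apply(lambda r: bool(groups_of(r) & set(group_filter)), axis=1) \
            if len(df) else pd.Series(dtype=bool)
        df = df[keep]
    out = df[["variant", "position", "homozygote_count", "hemizygote_count"]].copy()
    out["hemizygous_only"] = (out["homozygote_count"] == 0) & (out["hemizygote_count"] > 0)
    return out.reset_index(drop=True)


def population_enrichment(
    sub_catalog: pd.DataFrame, full_gnomad: pd.DataFrame
) -> pd.DataFrame:
    """Tally max-AF populations of filtered variants against the gnomAD background.

    For each population label, counts filtered variants whose maximum allele
    frequency occurs in that population, alongside the proportion of all
    gnomAD-listed variants with that max-AF population.
    """
    fg = full_gnomad[full_gnomad["max_af_population"].notna()]
    bg = fg["max_af_population"].value_counts()
    fil = sub_catalog["max_af_population"].value_counts() if len(sub_catalog) else pd.Series(dtype=int)
    pops = sorted(set(bg.index) | set(fil.index))
    total_bg = int(bg.sum()) or 1
    rows = [
        {
            "population": p,
            "filtered_count": int(fil.get(p, 0)),
            "background_count": int(bg.get(p, 0)),
            "background_proportion": bg.get(p, 0) / total_bg,
        }
        for p in pops
    ]
    return pd.DataFrame(rows)
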