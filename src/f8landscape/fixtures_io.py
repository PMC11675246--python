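"""Loader for the packaged desk-scale reference tables.

The package ships three small delimited fixtures: the conserved-yet-common
variant table (18 rows), the 41-row VUS shortlist with total scores, and the
printed per-cluster motion-correlation partner lists, plus the 12-member
co-inherited eQTL block (rsIDs and genomic bounds on both genome builds).
Each file is verified against a stored SHA-256 checksum at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import FixtureError

_PKG = "f8landscape.fixtures"


def _read_bytes(name: str) -> bytes:
    return resources.files(_PKG).joinpath(name).read_bytes()


def _verified_bytes(name: str) -> bytes:
    data = _read_bytes(name)
    sums = json.loads(_read_bytes("checksums.json"))
    digest = hashlib.sha256(data).hexdigest()
    if sums.get(name) != digest:
        raise FixtureError(f"checksum mismatch for fixture {name}")
    return data


@dataclass
class FixtureBundle:
    """Typed access to the packaged reference tables."""

    table1: pd.DataFrame            # conserved & common variants
    table2: pd.DataFrame            # VUS shortlist with total scores
    cluster_members: pd.DataFrame   # cluster id -> VUS residues
    cluster_correlations: pd.DataFrame  # printed partner/correlation lists
    ld_block: dict                  # rsIDs + hg38/hg19 bounds


def table1_as_catalog(bundle: FixtureBundle) -> pd.DataFrame:
    """Conserved/common fixture table in harmonized-catalog column layout."""
    from .catalog import parse_variant

    df = bundle.table1.copy()
    parsed = df["variant"].map(parse_variant)
    df["ref_aa"] = parsed.map(lambda t: t[0])
    df["position"] = parsed.map(lambda t: t[1])
    df["alt_aa"] = parsed.map(lambda t: t[2])
    df["source_groups"] = df["group"]
    df["max_af"] = df["gnomad_max_af"]
    df["overall_af"] = df["gnomad_overall_af"]
    df["homozygote_count"] = df["gnomad_homozygote"]
    df["hemizygote_count"] = df["gnomad_hemizygote"]
    return df


def table2_as_catalog(bundle: FixtureBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    """VUS-shortlist fixture as (catalog, totals) frames for re-ranking."""
    from .catalog import parse_variant

    df = bundle.table2.copy()
    parsed = df["variant"].map(parse_variant)
    df["position"] = parsed.map(lambda t: t[1])
    df["source_groups"] = df["group"]
    totals = df[["variant"]].copy()
    totals["total"] = df["total_score"]
    return df, totals


def load_paper_fixtures() -> FixtureBundle:
    """Load and checksum-verify every packaged fixture."""
    import io

    def _tsv(name: str) -> pd.DataFrame:
        return pd.read_csv(io.BytesIO(_verified_bytes(name)), sep="\t")

    return FixtureBundle(
        table1=_tsv("table1_conserved_common.tsv"),
        table2=_tsv("table2_vus_shortlist.tsv"),
        cluster_members=_tsv("cluster_members.tsv"),
        cluster_correlations=_tsv("cluster_correlations.tsv"),
        ld_block=json.loads(_verified_bytes("ld_block.json")),
    )
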