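"""Additive multi-evidence pathogenicity scoring.

Each missense variant is scored by summing three kinds of evidence on a
common scale: the conservation score of its position (in [0, 1]), a binary
annotation marking a post-translational-modification or cleavage site, and
one normalized score per prediction tool (each mapped to [0, 1], oriented so
larger means more damaging). With twelve tools the total lies in [0, 14].
Variants of uncertain significance whose total falls within the range spanned
by known-pathogenic variants are shortlisted for re-evaluation; the low edge
of that range is taken as a quantile of the pathogenic total-score
distribution.

The normalization maps are package defaults derived from each tool's
published score range and orientation; they are overridable per run, and rank
ordering rather than any absolute total is the quantity of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, UnknownToolError


@dataclass(frozen=True)
class LinearMap:
    """Affine map of a raw tool score onto [0, 1], damaging-high orientation.

    ``normalize(x) = clip((x - lo) / (hi - lo))``, flipped to
    ``1 - clip(...)`` when ``flip`` is set (for tools where low raw values
    mean damaging, e.g. SIFT and PROVEAN).
    """

    lo: float
    hi: float
    flip: bool = False

    def normalize(self, raw: float) -> float:
        z = (raw - self.lo) / (self.hi - self.lo)
        z = min(1.0, max(0.0, z))
        return 1.0 - z if self.flip else z

    def denormalize(self, norm: float) -> float:
        z = 1.0 - norm if self.flip else norm
        return self.lo + z * (self.hi - self.lo)


#: Default per-tool maps: (lo, hi) span the tool's published range; flip
#: marks damaging-low tools. CADD PHRED saturates at 40, MutationAssessor at
#: 5.5, GERP++ RS spans [-12.3, 6.2], PROVEAN [-14, 2.5] (damaging-low).
TOOL_NORMALIZATIONS: dict[str, LinearMap] = {
    "CADD_PHRED": LinearMap(0.0, 40.0),
    "SIFT": LinearMap(0.0, 1.0, flip=True),
    "PolyPhen": LinearMap(0.0, 1.0),
    "MutationAssessor": LinearMap(0.0, 5.5),
    "ClinPred": LinearMap(0.0, 1.0),
    "DANN": LinearMap(0.0, 1.0),
    "GERP++_RS": LinearMap(-12.3, 6.2),
    "GenoCanyon": LinearMap(0.0, 1.0),
    "LIST-S2": LinearMap(0.0, 1.0),
    "MVP": LinearMap(0.0, 1.0),
    "PROVEAN": LinearMap(-14.0, 2.5, flip=True),
    "REVEL": LinearMap(0.0, 1.0),
}


def normalize_tool(
    tool_name: str,
    raw_value: float,
    maps: dict[str, LinearMap] | None = None,
) -> float:
    """Map a raw prediction-tool score to [0, 1], larger = more damaging."""
    maps = maps if maps is not None else TOOL_NORMALIZATIONS
    if tool_name not in maps:
        raise UnknownToolError(tool_name)
    return maps[tool_name].normalize(float(raw_value))


def denormalize_tool(
    tool_name: str,
    norm_value: float,
    maps: dict[str, LinearMap] | None = None,
) -> float:
    """Inverse of :func:`normalize_tool` (used by the synthetic generator)."""
    maps = maps if maps is not None else TOOL_NORMALIZATIONS
    if tool_name not in maps:
        raise UnknownToolError(tool_name)
    return maps[tool_name].denormalize(float(norm_value))


@dataclass
class TotalScore:
    """Summed evidence score for one variant.

    ``total`` equals ``conservation + site_annotation + sum(tool_components)``
    exactly; missing tool scores contribute 0 and set ``has_missing``.
    """

    variant: str
    conservation: float
    site_annotation: int
    tool_components: dict[str, float]
    has_missing: bool

    @property
    def total(self) -> float:
        return self.conservation + self.site_annotation + sum(self.tool_components.values())


def total_score(
    panel_row: dict[str, float],
    conservation: float,
    site_annotation: int = 0,
    maps: dict[str, LinearMap] | None = None,
    variant: str = "",
) -> TotalScore:
    """Sum conservation, the binary site annotation, and normalized tool scores.

    ``panel_row`` maps tool names to raw scores; tools absent or NaN are
    treated as missing and contribute 0 (the total is then a lower bound, and
    the record is flagged).
    """
    maps = maps if maps is not None else TOOL_NORMALIZATIONS
    components: dict[str, float] = {}
    missing = False
    for tool in maps:
        raw = panel_row.get(tool)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            missing = True
            continue
        components[tool] = normalize_tool(tool, raw, maps)
    return TotalScore(
        variant=variant or str(panel_row.get("variant", "")),
        conservation=float(conservation),
        site_annotation=int(site_annotation),
        tool_components=components,
        has_missing=missing,
    )


def score_panel(
    panel: pd.DataFrame,
    conservation_by_variant: dict[str, float] | pd.Series,
    sites_by_variant: dict[str, int] | pd.Series | None = None,
    maps: dict[str, LinearMap] | None = None,
) -> pd.DataFrame:
    """Score every row of a tool-score panel; returns a total-score table.

    The panel must have a ``variant`` column plus one column per tool.
    Returns a DataFrame with columns ``variant``, ``total``, ``conservation``,
    ``site_annotation``, ``has_missing`` and one ``norm_<tool>`` column per
    tool in the normalization map.
    """
    maps = maps if maps is not None else TOOL_NORMALIZATIONS
    sites_by_variant = sites_by_variant or {}
    rows = []
    for _, r in panel.iterrows():
        v = str(r["variant"])
        cons = float(conservation_by_variant[v])
        site = int(sites_by_variant.get(v, 0)) if not isinstance(sites_by_variant, pd.Series) \
            else int(sites_by_variant.get(v, 0))
        ts = total_score(r.to_dict(), cons, site, maps, variant=v)
        row = {"variant": v, "total": ts.total, "conservation": cons,
               "site_annotation": site, "has_missing": ts.has_missing}
        for tool in maps:
            row[f"norm_{tool}"] = ts.tool_components.get(tool, np.nan)
        rows.append(row)
    cols = ["variant", "total", "conservation", "site_annotation", "has_missing"] + [
        f"norm_{t}" for t in maps
    ]
    return pd.DataFrame(rows, columns=cols)


def pathogenic_range_threshold(pathogenic_scores, quantile: float = 0.05) -> float:
    """Low edge of the known-pathogenic total-score range.

    Returns the given quantile (linear interpolation) of the pathogenic
    total-score distribution; VUS scoring at or above it fall "within the
    pathogenic range".
    """
    scores = np.asarray(list(pathogenic_scores), dtype=float)
    if scores.size == 0:
        raise EmptyInputError("no pathogenic scores supplied")
    if scores.size < 2:
        raise EmptyInputError("need at least 2 pathogenic scores for a range")
    return float(np.quantile(scores, quantile))


def shortlist_vus(
    catalog: pd.DataFrame,
    totals: pd.DataFrame,
    threshold: float,
    eligible_groups: frozenset[str] = frozenset({"ClinVar_VUS", "Geno2MP"}),
) -> pd.DataFrame:
    """Rank uncertain variants whose total score reaches the pathogenic range.

    ``catalog`` needs ``variant``, ``position`` and ``source_groups`` (a
    set-valued or comma-joined column); ``totals`` is the output of
    :func:`score_panel`. Eligible records belong to at least one of
    ``eligible_groups`` and not to ClinVar_Path; those with
    ``total >= threshold`` are returned sorted by total descending, ties by
    position ascending.
    """
    merged = catalog.drop(columns=["total"], errors="ignore").merge(
        totals[["variant", "total"]], on="variant", how="inner"
    )

    def _groups(v) -> set[str]:
        if isinstance(v, str):
            return {g.strip() for g in v.split(",") if g.strip()}
        return set(v)

    gsets = merged["source_groups"].map(_groups)
    ok = gsets.map(lambda s: bool(s & eligible_groups) and "ClinVar_Path" not in s)
    hits = merged[ok & (merged["total"] >= threshold)].copy()
    hits = hits.sort_values(
        ["total", "position"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return hits
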