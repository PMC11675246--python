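"""Co-inherited eQTL block detection from association summary statistics.

Variants in strong linkage disequilibrium that tag the same expression signal
show near-identical -log10 p-values and normalized effect sizes in an eQTL
scan. A block is therefore detected as a maximal group of variants whose
statistics agree pairwise within user-supplied tolerances and whose effect
sizes share a sign; its genomic span is the end-start base difference, which
is invariant to genome-build coordinate shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LDBlock:
    """A co-inherited variant group and its genomic extent."""

    rsids: list[str]
    start: int
    end: int
    effect_sign: int
    mean_minus_log10_p: float
    mean_effect_size: float

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def n_members(self) -> int:
        return len(self.rsids)


def block_span(block: LDBlock) -> int:
    """Genomic span in bases, as the end - start difference."""
    return block.span


def _best_group(df: pd.DataFrame, p_tol: float, effect_tol: float) -> list[int]:
    """Largest index set with pairwise-similar stats and a shared effect sign.

    Pairwise |delta| <= tol over a set is equivalent to range <= tol, so for
    each candidate -log10 p window the best effect-size window is found by a
    two-pointer sweep. Ties prefer the earlier window for determinism.
    """
    best: list[int] = []
    for sign in (1, -1):
        sub = df[np.sign(df["effect_size"]) == sign]
        if len(sub) <= len(best):
            continue
        byp = sub.sort_values(["minus_log10_p", "pos"], kind="stable")
        mlp = byp["minus_log10_p"].to_numpy()
        for i in range(len(byp)):
            in_p = byp[(mlp >= mlp[i]) & (mlp <= mlp[i] + p_tol)]
            if len(in_p) <= len(best):
                continue
            bye = in_p.sort_values(["effect_size", "pos"], kind="stable")
            eff = bye["effect_size"].to_numpy()
            lo = 0
            for hi in range(len(bye)):
                while eff[hi] - eff[lo] > effect_tol:
                    lo += 1
                if hi - lo + 1 > len(best):
                    best = list(bye.index[lo : hi + 1])
    return best


def detect_block(
    records: pd.DataFrame,
    p_tolerance: float,
    effect_tolerance: float,
    min_members: int = 2,
) -> list[LDBlock]:
    """Find maximal co-inherited blocks in an eQTL summary table.

    ``records`` needs columns ``rsid``, ``pos``, ``minus_log10_p``,
    ``effect_size``. Blocks are extracted greedily largest-first (members are
    removed before searching again), so the returned blocks are disjoint;
    groups smaller than ``min_members`` are discarded and the result is
    sorted by span descending. Tolerances are deliberate inputs: block
    membership is meaningless without a stated similarity scale.
    """
    if records is None or len(records) == 0:
        return []
    df = records.reset_index(drop=True).copy()
    df = df[df["effect_size"] != 0]
    blocks: list[LDBlock] = []
    while True:
        members = _best_group(df, p_tolerance, effect_tolerance)
        if len(members) < max(min_members, 2):
            break
        grp = df.loc[members]
        blocks.append(
            LDBlock(
                rsids=list(grp.sort_values("pos")["rsid"]),
                start=int(grp["pos"].min()),
                end=int(grp["pos"].max()),
                effect_sign=int(np.sign(grp["effect_size"].iloc[0])),
                mean_minus_log10_p=float(grp["minus_log10_p"].mean()),
                mean_effect_size=float(grp["effect_size"].mean()),
            )
        )
        df = df.drop(index=members)
        if df.empty:
            break
    blocks.sort(key=lambda b: -b.span)
    return blocks


def blocks_frame(blocks: list[LDBlock]) -> pd.DataFrame:
    """Tabulate detected blocks for reporting."""
    return pd.DataFrame(
        [
            {
                "n_members": b.n_members, "start": b.start, "end": b.end,
                "span": b.span, "effect_sign": b.effect_sign,
                "mean_minus_log10_p": b.mean_minus_log10_p,
                "mean_effect_size": b.mean_effect_size,
                "rsids": ",".join(b.rsids),
            }
            for b in blocks
        ]
    )
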