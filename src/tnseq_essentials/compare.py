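"""Cross-condition comparison of gene essentiality calls.

Tn-seq pools grown under two conditions (originally glucose vs methanol
minimal media) yield two per-gene NEP profiles over the same gene universe.
A gene that is confidently non-essential under condition A (NEP_a above a
high cutoff) but needed under condition B (NEP_b below a low cutoff) is a
condition-B-specific essentiality candidate — in the original screen, genes
required for methanol metabolism or signaling but dispensable on glucose.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classifier import EssentialityRecord

__all__ = ["ConditionPair", "condition_specific_candidates", "compare_report"]


@dataclass
class ConditionPair:
    condition_a: str
    condition_b: str
    records_a: list[EssentialityRecord]
    records_b: list[EssentialityRecord]

    def __post_init__(self) -> None:
        if self.condition_a == self.condition_b:
            raise ValueError("condition names must be distinct")

    def harmonized(self):
        """Classified records over the shared gene universe.

        Genes excluded (low TA / marker / undefined) in either condition have
        no comparable NEP and are dropped; they are returned separately.
        Returns (records_a, records_b, dropped_gene_ids) with matching order.
        """
        a = {r.gene_id: r for r in self.records_a}
        b = {r.gene_id: r for r in self.records_b}
        if set(a) != set(b):
            diff = sorted(set(a) ^ set(b))
            raise ValueError(f"mismatched gene universes; symmetric difference: {diff}")
        dropped = sorted(
            g for g in a if a[g].category == "excluded" or b[g].category == "excluded"
        )
        kept = sorted(g for g in a if g not in set(dropped))
        return [a[g] for g in kept], [b[g] for g in kept], dropped


def condition_specific_candidates(
    pair: ConditionPair,
    nonessential_cutoff_a: float = 0.9,
    essential_cutoff_b: float = 0.5,
) -> pd.DataFrame:
    """Genes non-essential under A (NEP_a > cutoff_a) but needed under B
    (NEP_b < cutoff_b), sorted by NEP_b ascending (strongest candidates first)."""
    recs_a, recs_b, _ = pair.harmonized()
    rows = [
        {"gene_id": ra.gene_id, f"nep_{pair.condition_a}": ra.nep,
         f"nep_{pair.condition_b}": rb.nep}
        for ra, rb in zip(recs_a, recs_b)
        if ra.nep > nonessential_cutoff_a and rb.nep < essential_cutoff_b
    ]
    df = pd.DataFrame(rows, columns=["gene_id", f"nep_{pair.condition_a}",
                                     f"nep_{pair.condition_b}"])
    if len(df):
        df = df.sort_values(f"nep_{pair.condition_b}", kind="stable").reset_index(drop=True)
    return df


def compare_report(pair: ConditionPair) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-gene join of the two conditions plus a category cross-tab.

    The per-gene table has NEP and category under each condition and
    delta = NEP_b - NEP_a; the cross-tab counts (category_a, category_b)
    cells over the whole universe including exclusions.
    """
    a = {r.gene_id: r for r in pair.records_a}
    b = {r.gene_id: r for r in pair.records_b}
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise ValueError(f"mismatched gene universes; symmetric difference: {diff}")
    genes = sorted(a)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            f"nep_{pair.condition_a}": [a[g].nep for g in genes],
            f"nep_{pair.condition_b}": [b[g].nep for g in genes],
            f"category_{pair.condition_a}": [a[g].category for g in genes],
            f"category_{pair.condition_b}": [b[g].category for g in genes],
        }
    )
    table["delta"] = (
        table[f"nep_{pair.condition_b}"] - table[f"nep_{pair.condition_a}"]
    )
    crosstab = pd.crosstab(
        table[f"category_{pair.condition_a}"], table[f"category_{pair.condition_b}"]
    )
    return table, crosstab
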