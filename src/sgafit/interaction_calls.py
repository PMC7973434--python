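"""Significant-interaction sets, overlap accounting and the trifecta
classification of a mutant allele against a reference deletion.

An interaction is called when the BH-adjusted p-value of a mutant-control
contrast falls below alpha; the sign of the normalized colony-size
difference splits calls into positive (suppression) and negative (synthetic
sick) sets.  Comparing an allele A against both the control and a reference
deletion B partitions its signature: interactions shared with the deletion
(lost function), interactions reversed relative to the deletion (residual /
restored function), aggravated interactions (increased sensitivity), and
interactions unique to the allele (gained function).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .errors import StructuralError

CALL_COLUMNS = ["gene_id", "strain", "sign", "effect", "padj"]
TRIFECTA_CATEGORIES = [
    "shared_positive",
    "shared_negative",
    "residual_restored",
    "increased_sensitivity",
    "unique_gain_positive",
    "unique_gain_negative",
    "none",
]


def call_interactions(
    fits: pd.DataFrame, alpha: float = 0.05, control: str | None = None
) -> pd.DataFrame:
    """Extract significant interactions from mutant-control contrasts.

    A gene is called iff padj < alpha (no effect-size floor); the sign of
    the effect labels the call positive or negative.  ``control`` defaults
    to the most common contrast suffix ("mutant-control" naming).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    parts = fits["contrast"].str.rsplit("-", n=1, expand=True)
    if parts.shape[1] != 2 or parts[1].isna().any():
        raise StructuralError("contrast names must look like 'mutant-control'")
    if control is None:
        control = parts[1].mode().iloc[0]
    sub = fits[parts[1] == control].copy()
    sub["strain"] = parts.loc[sub.index, 0]
    called = sub[sub["padj"] < alpha].copy()
    called["sign"] = np.where(called["effect"] > 0, "positive", "negative")
    return called[CALL_COLUMNS].reset_index(drop=True)


def overlap_counts(
    calls: pd.DataFrame, sign_consistent: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strain call counts and shared counts for every strain combination.

    Returns ``(per_strain, shared)``: per_strain has n_positive, n_negative,
    n_total and n_unique (genes called in no other strain); shared has one
    row per pair/triple/... of strains with the intersection size.  With
    ``sign_consistent`` a gene only counts as shared when its sign agrees in
    all members of the combination.
    """
    strains = sorted(calls["strain"].unique())
    if len(strains) < 2:
        raise ValueError("need calls for at least 2 strains")
    gene_sets = {s: set(calls.loc[calls["strain"] == s, "gene_id"]) for s in strains}
    signed_sets = {
        s: set(zip(calls.loc[calls["strain"] == s, "gene_id"],
                   calls.loc[calls["strain"] == s, "sign"]))
        for s in strains
    }
    per_rows = []
    for s in strains:
        sub = calls[calls["strain"] == s]
        others = set().union(*(gene_sets[o] for o in strains if o != s))
        per_rows.append(
            (
                s,
                int((sub["sign"] == "positive").sum()),
                int((sub["sign"] == "negative").sum()),
                len(sub),
                len(gene_sets[s] - others),
            )
        )
    per_strain = pd.DataFrame(
        per_rows, columns=["strain", "n_positive", "n_negative", "n_total", "n_unique"]
    )
    shared_rows = []
    for r in range(2, len(strains) + 1):
        for combo in combinations(strains, r):
            if sign_consistent:
                inter = set.intersection(*(signed_sets[s] for s in combo))
                count = len({g for g, _ in inter})
            else:
                inter = set.intersection(*(gene_sets[s] for s in combo))
                count = len(inter)
            shared_rows.append(("&".join(combo), r, count))
    shared = pd.DataFrame(shared_rows, columns=["strains", "order", "n_shared"])
    return per_strain, shared


def classify_trifecta(
    fitA: pd.DataFrame, fitB: pd.DataFrame, fitD: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Classify every gene by comparing allele A to reference B and control.

    ``fitA`` is allele-control, ``fitB`` reference-control, ``fitD``
    allele-reference, each with one row per gene.  First matching rule wins:

    1. unique_gain_{sign}: D significant and B not (sign from A's effect,
       falling back to D when A's effect is zero);
    2. residual_restored: D and B significant with opposite signs;
    3. increased_sensitivity: D and B significant with the same sign;
    4. shared_{sign}: A and B significant, same sign, D not significant;
    5. none.
    """
    frames = {}
    for name, f in (("A", fitA), ("B", fitB), ("D", fitD)):
        frames[name] = f.set_index("gene_id")[["effect", "padj"]].rename(
            columns={"effect": f"effect_{name}", "padj": f"padj_{name}"}
        )
    universes = [set(f.index) for f in frames.values()]
    if universes[0] != universes[1] or universes[0] != universes[2]:
        raise StructuralError("the three contrasts cover different gene universes")
    table = frames["A"].join(frames["B"]).join(frames["D"])

    sigA = table["padj_A"] < alpha
    sigB = table["padj_B"] < alpha
    sigD = table["padj_D"] < alpha
    sA = np.sign(table["effect_A"])
    sB = np.sign(table["effect_B"])
    sD = np.sign(table["effect_D"])
    gain_sign = np.where(sA != 0, sA, sD)

    category = np.full(len(table), "none", dtype=object)
    rule_shared = sigA & sigB & (sA == sB) & ~sigD
    category[rule_shared & (sA > 0)] = "shared_positive"
    category[rule_shared & (sA < 0)] = "shared_negative"
    rule_incr = sigD & sigB & (sD == sB)
    category[rule_incr] = "increased_sensitivity"
    rule_resid = sigD & sigB & (sD == -sB) & (sD != 0)
    category[rule_resid] = "residual_restored"
    rule_gain = sigD & ~sigB
    category[rule_gain & (gain_sign > 0)] = "unique_gain_positive"
    category[rule_gain & (gain_sign <= 0)] = "unique_gain_negative"

    out = table.reset_index()
    out.insert(1, "category", category)
    return out


def volcano2d_table(fitX: pd.DataFrame, fitY: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table for a comparative 2D volcano (biplot of two contrasts).

    Per gene: both effects, a combined significance score (the more
    significant of the two adjusted p-values on a -log10 scale) and the
    quadrant label.
    """
    x = fitX.set_index("gene_id")[["effect", "padj"]].rename(
        columns={"effect": "effect_x", "padj": "padj_x"}
    )
    y = fitY.set_index("gene_id")[["effect", "padj"]].rename(
        columns={"effect": "effect_y", "padj": "padj_y"}
    )
    if set(x.index) != set(y.index):
        raise StructuralError("the two contrasts cover different gene universes")
    table = x.join(y)
    with np.errstate(divide="ignore"):
        table["score"] = -np.log10(np.minimum(table["padj_x"], table["padj_y"]))
    ex, ey = table["effect_x"], table["effect_y"]
    quadrant = np.select(
        [
            (ex > 0) & (ey > 0),
            (ex < 0) & (ey < 0),
            (ex < 0) & (ey > 0),
            (ex > 0) & (ey < 0),
        ],
        ["upper_right", "lower_left", "upper_left", "lower_right"],
        default="none",
    )
    table["quadrant"] = quadrant
    return table.reset_index()
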