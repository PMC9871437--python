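"""Differential-distribution calling: genes that switch family label
between biological conditions.

A differentially distributed (DD) gene is one whose best-fit family differs
between conditions — a change of distribution *shape*, as opposed to the
mean shift of classical differential expression.  Switches are categorized
by the unimodal {P, NB} vs zero-inflated {ZIP, ZINB} partition.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .distributions import UNIMODAL, ZERO_INFLATED, zero_probability

log = logging.getLogger(__name__)

SWITCH_CATEGORIES = (
    "unimodal_to_zero_inflated",
    "zero_inflated_to_unimodal",
    "within_unimodal",
    "within_zero_inflated",
    "none",
)


def categorize_switch(label_a: str, label_b: str) -> str:
    """Category of the ordered label pair (a -> b)."""
    for lab in (label_a, label_b):
        if lab not in UNIMODAL and lab not in ZERO_INFLATED:
            raise ValueError(f"cannot categorize label {lab!r}")
    if label_a == label_b:
        return "none"
    a_uni = label_a in UNIMODAL
    b_uni = label_b in UNIMODAL
    if a_uni and not b_uni:
        return "unimodal_to_zero_inflated"
    if not a_uni and b_uni:
        return "zero_inflated_to_unimodal"
    return "within_unimodal" if a_uni else "within_zero_inflated"


def identify_switches(
    calls: pd.DataFrame, comparisons: list[tuple[str, str]] | str = "global"
) -> pd.DataFrame:
    """Per-gene shape-switch table.

    ``calls`` needs columns gene, condition, label.  ``comparisons`` is a
    list of ordered condition pairs, or "global" for all pairs.  A gene
    enters a comparison only if it has a non-FAILED call in every compared
    condition; ``is_dd`` flags any label disagreement across all compared
    conditions.
    """
    wide = calls.pivot(index="gene", columns="condition", values="label")
    conditions = list(wide.columns)
    if comparisons == "global":
        pairs = list(itertools.combinations(conditions, 2))
    else:
        pairs = [tuple(p) for p in comparisons]
        for a, b in pairs:
            for c in (a, b):
                if c not in conditions:
                    raise ValueError(f"comparison names condition {c!r} with no calls")

    compared = sorted({c for p in pairs for c in p})
    sub = wide[compared]
    ok = sub.notna().all(axis=1) & (sub != "FAILED").all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("excluding %d genes with FAILED/absent calls in a compared condition",
                 n_excluded)
    sub = sub[ok]

    out = pd.DataFrame(index=sub.index)
    for cond in compared:
        out[f"label_{cond}"] = sub[cond]
    out["is_dd"] = sub.nunique(axis=1) > 1
    for a, b in pairs:
        out[f"switch_{a}_vs_{b}"] = sub[a] != sub[b]
        out[f"category_{a}_vs_{b}"] = [
            categorize_switch(la, lb) for la, lb in zip(sub[a], sub[b])
        ]
    return out.reset_index()


def extract_structural_zeros(calls: pd.DataFrame, counts_by_gene: dict[str, np.ndarray],
                             fits: dict[tuple[str, str], object]) -> pd.DataFrame:
    """For genes called ZIP/ZINB, report the structural-zero probability
    omega_hat next to the observed zero fraction, plus the structural share
    of the zeros, omega_hat / P(Y=0 | fit) (a derived convenience ratio)."""
    rows = []
    zi = calls[calls["label"].isin(ZERO_INFLATED)]
    for _, row in zi.iterrows():
        gene, cond = row["gene"], row["condition"]
        fit = fits.get((gene, cond))
        if fit is None:
            continue
        y = counts_by_gene[gene]
        omega = fit.omega or 0.0
        p_zero = float(
            np.mean(zero_probability(fit.family, fit.mu_hat, phi=fit.phi, omega=omega))
        )
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "label": row["label"],
                "omega_hat": omega,
                "observed_zero_fraction": float(np.mean(np.asarray(y) == 0)),
                "model_zero_probability": p_zero,
                "structural_share": omega / p_zero if p_zero > 0 else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "condition", "label", "omega_hat",
            "observed_zero_fraction", "model_zero_probability", "structural_share",
        ],
    )


def structural_share(omega: float, mu: float, phi: float | None, family: str) -> float:
    """omega / P(Y=0) for a scalar-mean zero-inflated fit."""
    p_zero = float(zero_probability(family, mu, phi=phi, omega=omega))
    return omega / p_zero if p_zero > 0 else 0.0
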