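"""Model/Results interface for the metabolizer-status association analysis.

:class:`MetabolizerAssociation` is built from per-patient analysis data —
trajectory label plus collapsed metabolizer group within one enzyme's
substrate subsample — or directly from an outcome count table.  ``fit()``
computes, for each non-reference group, the odds ratio of discontinuing
(and of switching) versus maintaining relative to the NM reference, with
Wald confidence intervals, and the post-hoc power of the corresponding
two-proportion comparison.  The result object carries the estimates and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import (
    ContingencyTable,
    PowerInput,
    ZeroCellError,
    expand_2x2,
    logistic_fit,
    odds_ratio_wald,
    power_two_proportions,
)

__all__ = ["MetabolizerAssociation", "AssociationResults"]

#: outcome contrasts analysed against the maintained reference
CONTRASTS = ("discontinued", "switched")


class MetabolizerAssociation:
    """Association of collapsed metabolizer group with trajectory outcome.

    Parameters
    ----------
    counts
        DataFrame indexed by group with columns for the maintained
        reference and the event outcomes (discontinued, switched).
    enzyme
        Label carried through to the results (e.g. ``"CYP2D6"``).
    reference_group
        Defaults to ``"NM"`` when present, else the first index entry.
    """

    def __init__(self, counts: pd.DataFrame, enzyme: str = "",
                 reference_group: str | None = None):
        if "maintained" not in counts.columns:
            raise ValueError("counts must include a 'maintained' column")
        if reference_group is None:
            reference_group = "NM" if "NM" in counts.index else counts.index[0]
        self.counts = counts.astype(int)
        self.enzyme = enzyme
        self.reference_group = reference_group

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        group_col: str = "group",
        label_col: str = "label",
        enzyme: str = "",
        reference_group: str | None = None,
    ) -> "MetabolizerAssociation":
        """Build from per-patient rows with a group and a trajectory label.

        Labels outside {maintained, discontinued, switched} (e.g.
        NOT_CLASSIFIABLE) and rows with a null group are dropped.
        """
        labels = data[label_col].astype(str).str.lower()
        keep = labels.isin(["maintained", *CONTRASTS]) & data[group_col].notna()
        counts = pd.crosstab(data.loc[keep, group_col], labels[keep])
        for col in ("maintained", *CONTRASTS):
            if col not in counts.columns:
                counts[col] = 0
        return cls(counts[["maintained", *CONTRASTS]], enzyme, reference_group)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, dict[str, int]],
        enzyme: str = "",
        reference_group: str | None = None,
    ) -> "MetabolizerAssociation":
        """Build from nested dicts group → outcome → count."""
        return cls(pd.DataFrame.from_dict(counts, orient="index"),
                   enzyme, reference_group)

    def fit(self, alpha: float = 0.05, method: str = "wald") -> "AssociationResults":
        """Estimate ORs for every group/contrast; ``method`` is ``"wald"``
        (closed form) or ``"logistic"`` (IRLS on expanded data — identical
        estimates on these saturated tables, used as a cross-check)."""
        rows = []
        skipped: list[str] = []
        ref = self.reference_group
        for contrast in CONTRASTS:
            if contrast not in self.counts.columns:
                continue
            sub = ContingencyTable(
                self.counts[["maintained", contrast]],
                reference_group=ref,
                reference_outcome="maintained",
            )
            for group in self.counts.index:
                if group == ref:
                    continue
                a = sub.cell(group, contrast)
                b = sub.cell(group, "maintained")
                c = sub.cell(ref, contrast)
                d = sub.cell(ref, "maintained")
                base = {
                    "enzyme": self.enzyme,
                    "contrast": contrast,
                    "group": group,
                    "n_event": a,
                    "n_maintained": b,
                    "ref_event": c,
                    "ref_maintained": d,
                }
                if min(a, b, c, d) == 0:
                    skipped.append(f"{self.enzyme} {group} {contrast}: zero cell")
                    continue
                if method == "wald":
                    est = odds_ratio_wald(sub, group, contrast, alpha=alpha)
                    or_, lo, hi, p = (est.odds_ratio, est.ci_low,
                                      est.ci_high, est.p_value)
                elif method == "logistic":
                    y, x = expand_2x2(a, b, c, d)
                    res = logistic_fit(y, x, names=["group"])
                    or_ = float(np.exp(res.params[1]))
                    ci = res.conf_int(alpha)[1]
                    lo, hi = float(ci[0]), float(ci[1])
                    p = float(res.summary_frame(alpha)["p_value"].iloc[1])
                else:
                    raise ValueError(f"unknown method {method!r}")
                power = power_two_proportions(
                    PowerInput(p1=c / (c + d), p2=a / (a + b),
                               n1=c + d, n2=a + b, alpha=alpha)
                )
                rows.append({**base, "odds_ratio": or_, "ci_low": lo,
                             "ci_high": hi, "p_value": p, "power": power})
        table = pd.DataFrame(rows)
        return AssociationResults(model=self, estimates=table, alpha=alpha,
                                  method=method, skipped=skipped)


@dataclass
class AssociationResults:
    """Fitted odds ratios, intervals and post-hoc power for one enzyme."""

    model: MetabolizerAssociation
    estimates: pd.DataFrame
    alpha: float
    method: str
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> str:
        """Human-readable table mirroring the published report layout:
        percentages at 1 decimal, ORs/CIs and power at 2."""
        lines = []
        enzyme = self.model.enzyme or "enzyme"
        counts = self.model.counts
        lines.append(f"{enzyme} substrate users (n = {int(counts.to_numpy().sum())})")
        totals = counts.sum(axis=1)
        header = f"{'group':<10}" + "".join(
            f"{c:>20}" for c in counts.columns
        )
        lines.append(header)
        for group in counts.index:
            cells = []
            for col in counts.columns:
                n = counts.loc[group, col]
                pct = 100.0 * n / totals[group] if totals[group] else 0.0
                cells.append(f"{n} ({pct:.1f}%)".rjust(20))
            lines.append(f"{group:<10}" + "".join(cells))
        lines.append("")
        if self.estimates.empty:
            lines.append("no estimable contrasts")
        else:
            lines.append(
                f"{'contrast':<14}{'group':<10}{'OR':>8}"
                f"{'95% CI':>18}{'power':>8}"
            )
            for row in self.estimates.itertuples():
                lines.append(
                    f"{row.contrast:<14}{row.group:<10}{row.odds_ratio:>8.2f}"
                    + f"({row.ci_low:.2f} - {row.ci_high:.2f})".rjust(18)
                    + f"{row.power:>8.2f}"
                )
        for msg in self.skipped:
            lines.append(f"skipped: {msg}")
        return "\n".join(lines)

    def power_range(self) -> tuple[float, float]:
        """Smallest and largest post-hoc power over estimated contrasts."""
        if self.estimates.empty:
            raise ZeroCellError("no estimable contrasts")
        return (float(self.estimates["power"].min()),
                float(self.estimates["power"].max()))
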