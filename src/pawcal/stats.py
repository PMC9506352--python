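"""Group statistics: pairwise Student's t-tests, compact letter display,
dose-response aggregation.

The assay's figures compare treatment groups (typically 6 seedlings each)
with plain two-sample Student's t-tests at alpha = 0.05 and summarise the
outcome with letters: groups sharing no letter differ significantly.  That
convention is reproduced faithfully — pooled-variance t-test, no
multiple-testing correction — with Welch's test and Holm adjustment
available behind flags for users who want them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTable",
    "LetterDisplay",
    "pairwise_tests",
    "letter_display",
    "build_dose_response",
]


@dataclass
class GroupTable:
    """Replicate values of one metric per treatment group, in display order."""

    values: dict  # label -> 1-D array of replicate values

    def __post_init__(self) -> None:
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for label, v in self.values.items():
            if v.ndim != 1 or v.size < 2:
                raise ValueError(f"group {label!r}: need >= 2 replicates")

    @property
    def labels(self) -> list:
        return list(self.values)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "group": label,
                "n": v.size,
                "mean": float(np.mean(v)),
                "se": float(np.std(v, ddof=1) / np.sqrt(v.size)),
            }
            for label, v in self.values.items()
        ]
        return pd.DataFrame(rows).set_index("group")


@dataclass
class LetterDisplay:
    """Letters per group: groups sharing a letter do not differ at ``alpha``."""

    letters: dict  # label -> string of letters, e.g. "ab"
    alpha: float = 0.05

    def share(self, a, b) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def pairwise_tests(
    table: GroupTable, welch: bool = False, holm: bool = False
) -> pd.DataFrame:
    """Two-sided p-value matrix for all unordered group pairs.

    Student's pooled-variance t-test by default (``welch=True`` switches to
    Welch's unequal-variance form).  Degenerate pairs with zero pooled
    variance get p = 1 if the means are equal, else p = 0.  ``holm=True``
    applies a Holm step-down adjustment across the pairs (off by default:
    the assay reports unadjusted tests).
    """
    labels = table.labels
    p = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    pairs = list(itertools.combinations(labels, 2))
    raw = []
    for a, b in pairs:
        x, y = table.values[a], table.values[b]
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            pv = 1.0 if np.mean(x) == np.mean(y) else 0.0
            warnings.warn(f"zero pooled variance for pair ({a}, {b})", stacklevel=2)
        else:
            pv = float(sps.ttest_ind(x, y, equal_var=not welch).pvalue)
        raw.append(pv)
    if holm and raw:
        order = np.argsort(raw)
        m = len(raw)
        adj, running = [0.0] * m, 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        raw = adj
    for (a, b), pv in zip(pairs, raw):
        p.loc[a, b] = p.loc[b, a] = pv
    return p


def letter_display(p_matrix: pd.DataFrame, alpha: float = 0.05) -> LetterDisplay:
    """Compact letter display by the insert-and-absorb algorithm.

    Starting from a single letter covering all groups, each significant pair
    splits every letter column containing both members into two copies (one
    without each member); columns that become subsets of another are absorbed.
    By construction two groups share a letter iff their pairwise p-value is
    >= alpha.  Letters are assigned in group (input) order.
    """
    groups = list(p_matrix.index)
    columns: list[set] = [set(groups)]
    for a, b in itertools.combinations(groups, 2):
        if p_matrix.loc[a, b] < alpha:
            new_cols = []
            for col in columns:
                if a in col and b in col:
                    new_cols.append(col - {a})
                    new_cols.append(col - {b})
                else:
                    new_cols.append(col)
            # absorb: drop duplicates and proper subsets
            columns = []
            for i, col in enumerate(new_cols):
                absorbed = any(
                    (col < other) or (col == other and j < i)
                    for j, other in enumerate(new_cols)
                    if j != i
                )
                if col and not absorbed:
                    columns.append(col)
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: sorted(order[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g] += letter
    return LetterDisplay(letters={g: letters[g] for g in groups}, alpha=alpha)


def build_dose_response(
    metrics: pd.DataFrame,
    doses: pd.DataFrame,
    value_column: str = "auc",
    key: str = "treatment",
) -> pd.DataFrame:
    """Aggregate per-well metrics against transferred energy per unit mass.

    ``metrics`` holds one row per well with a treatment key and the metric
    (integrated Ca2+ by default); ``doses`` holds one row per treatment with
    at least ``energy_per_mass`` (J/kg) and optional source/frequency/
    activation-time descriptors.  Treatments lacking a dose record are
    excluded with a warning.  The result has one row per treatment (n, mean,
    SE) sorted by energy.
    """
    if key not in metrics.columns or value_column not in metrics.columns:
        raise ValueError(f"metrics must contain columns {key!r} and {value_column!r}")
    if key not in doses.columns or "energy_per_mass" not in doses.columns:
        raise ValueError(f"doses must contain columns {key!r} and 'energy_per_mass'")
    missing = set(metrics[key]) - set(doses[key])
    if missing:
        warnings.warn(
            f"treatments without dose records excluded: {sorted(missing)}", stacklevel=2
        )
    grouped = (
        metrics[metrics[key].isin(set(doses[key]))]
        .groupby(key)[value_column]
        .agg(n="count", mean="mean", se=lambda v: np.std(v, ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    out = doses.merge(grouped, on=key, how="inner")
    out = out.sort_values("energy_per_mass", kind="stable").reset_index(drop=True)
    return out
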