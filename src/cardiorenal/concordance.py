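"""Incidence tables, cross-criterion concordance and discordant sets.

The interesting clinical object is the group of patients KDIGO detects but
RIFLE or AKIN misses: K(+)R(-) (KDIGO-positive, RIFLE-negative), K(+)A(-)
(KDIGO-positive, AKIN-negative), and their union. On series that never dip
below baseline KDIGO detects exactly the union of RIFLE and AKIN cases, so
|K(+)R(-)| = |KDIGO| - |RIFLE| and |K(+)A(-)| = |KDIGO| - |AKIN|.

Percentages are reported to one decimal with half-up rounding against two
denominators: the full retained cohort and, where indicated, the
KDIGO-positive count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .classify import CRITERIA, ClassificationTable

__all__ = [
    "pct",
    "incidence_table",
    "concordance_matrix",
    "discordant_sets",
    "ConcordanceReport",
    "build_report",
]


def pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, half-up (so 10.25% prints as 10.3)."""
    if denominator == 0:
        raise ValueError("empty denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _stages(table: ClassificationTable, criterion: str) -> pd.Series:
    return pd.Series(
        {pid: row.get(criterion).stage for pid, row in table.rows.items()}, dtype=int
    )


def incidence_table(table: ClassificationTable) -> pd.DataFrame:
    """Counts and cohort percentages per criterion, overall and per stage.

    Rows with ``stage == "all"`` give the overall detected count.
    """
    if len(table) == 0:
        raise ValueError("empty classification table")
    n = len(table)
    records = []
    for criterion in CRITERIA:
        stages = _stages(table, criterion)
        detected = int((stages >= 1).sum())
        records.append(
            {"criterion": criterion, "stage": "all", "n": detected, "pct_cohort": pct(detected, n)}
        )
        for s in (1, 2, 3):
            cnt = int((stages == s).sum())
            records.append(
                {"criterion": criterion, "stage": str(s), "n": cnt, "pct_cohort": pct(cnt, n)}
            )
    sets = discordant_sets(table)
    union = sets["union"]
    records.append(
        {
            "criterion": "K(+)R(-)+K(+)A(-)",
            "stage": "all",
            "n": len(union),
            "pct_cohort": pct(len(union), n),
        }
    )
    kdigo_stages = _stages(table, "KDIGO")
    for s in (1, 2, 3):
        cnt = int(sum(1 for pid in union if kdigo_stages[pid] == s))
        records.append(
            {
                "criterion": "K(+)R(-)+K(+)A(-)",
                "stage": str(s),
                "n": cnt,
                "pct_cohort": pct(cnt, n),
            }
        )
    return pd.DataFrame.from_records(records)


def concordance_matrix(table: ClassificationTable, other: str) -> pd.DataFrame:
    """4x4 cross-tabulation of KDIGO stage (rows) against another criterion.

    Stage 0 ("no AKI") is included so the matrix partitions the cohort.
    """
    if other not in ("RIFLE", "AKIN"):
        raise ValueError("comparison criterion must be 'RIFLE' or 'AKIN'")
    kdigo = _stages(table, "KDIGO")
    theirs = _stages(table, other)
    counts = np.zeros((4, 4), dtype=int)
    for pid in table.rows:
        counts[kdigo[pid], theirs[pid]] += 1
    idx = pd.Index([0, 1, 2, 3], name="kdigo_stage")
    cols = pd.Index([0, 1, 2, 3], name=f"{other.lower()}_stage")
    return pd.DataFrame(counts, index=idx, columns=cols)


def discordant_sets(table: ClassificationTable) -> dict[str, set[str]]:
    """K(+)R(-), K(+)A(-), their union, and the triple-positive set."""
    k_pos = {pid for pid, r in table.rows.items() if r.kdigo.detected}
    r_pos = {pid for pid, r in table.rows.items() if r.rifle.detected}
    a_pos = {pid for pid, r in table.rows.items() if r.akin.detected}
    return {
        "kdigo_not_rifle": k_pos - r_pos,
        "kdigo_not_akin": k_pos - a_pos,
        "union": k_pos - (r_pos & a_pos),
        "all_three_positive": k_pos & r_pos & a_pos,
    }


@dataclass
class ConcordanceReport:
    """Bundled incidence, cross-tabs and discordant-set sizes."""

    n_cohort: int
    incidence: pd.DataFrame
    cross_tabs: dict[str, pd.DataFrame]
    discordant: dict[str, set[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        payload = {
            "n_cohort": self.n_cohort,
            "incidence": self.incidence.to_dict(orient="records"),
            "cross_tabs": {
                name: df.values.tolist() for name, df in self.cross_tabs.items()
            },
            "discordant_counts": {k: len(v) for k, v in self.discordant.items()},
            "discordant_pct_cohort": {
                k: pct(len(v), self.n_cohort) for k, v in self.discordant.items()
            },
        }
        n_kdigo = len(self.discordant.get("union", set())) + len(
            self.discordant.get("all_three_positive", set())
        )
        if n_kdigo:
            payload["discordant_pct_kdigo"] = {
                k: pct(len(v), n_kdigo)
                for k, v in self.discordant.items()
                if k in ("kdigo_not_rifle", "kdigo_not_akin", "union")
            }
        return payload

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_report(table: ClassificationTable) -> ConcordanceReport:
    """Compute the full concordance report for a classified cohort."""
    return ConcordanceReport(
        n_cohort=len(table),
        incidence=incidence_table(table),
        cross_tabs={
            "kdigo_vs_rifle": concordance_matrix(table, "RIFLE"),
            "kdigo_vs_akin": concordance_matrix(table, "AKIN"),
        },
        discordant=discordant_sets(table),
    )
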