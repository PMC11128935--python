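"""CO2 respirometry screening statistics.

Sealed-bottle screens measure fungal mineralisation of plastic as CO2
accumulation, expressed as a percent of the bottle's total gas phase.
Each strain is incubated in triplicate with and without plastic;
uninoculated blank bottles (again with and without plastic) measure
abiotic CO2.  The screen:

1. subtracts the mean of the matched blanks (plastic-containing bottles
   use plastic-containing blanks, plastic-free bottles use medium-only
   blanks);
2. averages the biological triplicates per condition;
3. where the with-plastic mean exceeds the without-plastic mean, tests
   the increase with a one-tailed pooled-variance (Student) t-test;
   decreases are recorded but never tested;
4. classes each strain/condition as ``decrease``, ``increase_ns``,
   ``increase_p05`` (p < 0.05) or ``increase_p01`` (p < 0.01).

No multiple-testing correction is applied by default; a
Benjamini-Hochberg column can be added to reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RespirometrySample",
    "ScreeningRecord",
    "BlankMatchingError",
    "PairingError",
    "read_respirometry_table",
    "blank_correct",
    "compare_conditions",
    "screen_batch",
    "count_significant",
    "screening_table",
    "screening_summary",
]

CONDITIONS = ("none", "mixed", "LDPE", "PA", "PET", "PP", "PU")

CLASS_ORDER = {"decrease": 0, "increase_ns": 1, "increase_p05": 2, "increase_p01": 3}


class BlankMatchingError(ValueError):
    """No blank bottles available for a sample's condition class."""


class PairingError(ValueError):
    """A strain lacks the with/without-plastic condition pair."""


@dataclass(frozen=True)
class RespirometrySample:
    """One bottle measurement.

    ``condition == "none"`` means no plastic in the bottle; ``"mixed"``
    is the five-polymer mixture used in first-pass screens.  Blanks are
    uninoculated and carry an empty ``strain_id``.
    """

    strain_id: str
    condition: str
    nacl_pct: float
    is_blank: bool
    replicate: int
    co2_pct: float

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.co2_pct < 0:
            raise ValueError(f"co2_pct must be >= 0, got {self.co2_pct}")
        if self.is_blank and self.strain_id:
            raise ValueError("blank bottles must have empty strain_id")

    @property
    def has_plastic(self) -> bool:
        return self.condition != "none"


@dataclass(frozen=True)
class ScreeningRecord:
    """Blank-corrected screening result for one strain x plastic condition."""

    strain_id: str
    condition_with: str
    nacl_pct: float
    mean_with: float
    sd_with: float
    mean_without: float
    sd_without: float
    delta: float
    t_stat: float | None
    df: int | None
    p_one_tailed: float | None
    cls: str
    flags: tuple = ()

    def significant(self, alpha: float) -> bool:
        if self.p_one_tailed is None:
            return False
        return self.p_one_tailed < alpha


def read_respirometry_table(path) -> list[RespirometrySample]:
    """Read a respirometry CSV with columns strain_id, condition,
    nacl_pct, is_blank, replicate, co2_pct."""
    table = pd.read_csv(Path(path), dtype={"strain_id": str})
    required = ["strain_id", "condition", "nacl_pct", "is_blank", "replicate", "co2_pct"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"respirometry table missing columns: {missing}")
    out = []
    for rec in table.to_dict("records"):
        co2 = float(rec["co2_pct"])
        if co2 < 0:
            raise ValueError(f"negative co2_pct {co2} for strain {rec['strain_id']!r}")
        raw_blank = rec["is_blank"]
        if isinstance(raw_blank, str):
            is_blank = raw_blank.strip().lower() in ("true", "1", "yes")
        else:
            is_blank = bool(raw_blank)
        sid = rec["strain_id"]
        out.append(
            RespirometrySample(
                strain_id="" if (pd.isna(sid) or is_blank) else str(sid),
                condition=str(rec["condition"]),
                nacl_pct=float(rec["nacl_pct"]),
                is_blank=is_blank,
                replicate=int(rec["replicate"]),
                co2_pct=co2,
            )
        )
    return out


def blank_correct(
    samples: Sequence[RespirometrySample],
    blanks: Sequence[RespirometrySample],
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the matched blank mean from each sample's CO2.

    Plastic-containing bottles are corrected by the mean of the
    plastic-containing blanks, plastic-free bottles by the medium-only
    blanks.  Returns ``(corrected, low_signal)`` where ``low_signal``
    flags values driven negative by the correction (retained, never
    clipped).
    """
    if not blanks:
        raise BlankMatchingError("no blank bottles supplied")
    blank_means = {}
    for has_plastic in (True, False):
        vals = [b.co2_pct for b in blanks if b.has_plastic == has_plastic]
        if vals:
            blank_means[has_plastic] = float(np.mean(vals))
    corrected = np.empty(len(samples))
    for i, s in enumerate(samples):
        if s.has_plastic not in blank_means:
            kind = "plastic-containing" if s.has_plastic else "medium-only"
            raise BlankMatchingError(
                f"no {kind} blanks available for strain {s.strain_id!r}, condition {s.condition!r}"
            )
        corrected[i] = s.co2_pct - blank_means[s.has_plastic]
    return corrected, corrected < 0


def compare_conditions(
    with_vals: Sequence[float],
    without_vals: Sequence[float],
    strain_id: str = "",
    condition_with: str = "mixed",
    nacl_pct: float = 0.0,
    welch: bool = False,
) -> ScreeningRecord:
    """Compare blank-corrected CO2 in with-plastic vs without-plastic bottles.

    The one-tailed test (alternative: with-plastic mean is larger) is run
    only when the with-plastic mean actually exceeds the without-plastic
    mean; otherwise the record is classed ``decrease`` with no p-value.
    The default is the pooled-variance Student t with ``df = n1+n2-2``;
    ``welch=True`` switches to the unequal-variance form.
    """
    a = np.asarray(with_vals, dtype=float)
    b = np.asarray(without_vals, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    mean_w, mean_wo = a.mean(), b.mean()
    sd_w = a.std(ddof=1)
    sd_wo = b.std(ddof=1)
    delta = mean_w - mean_wo
    flags = []

    if mean_w <= mean_wo:
        return ScreeningRecord(
            strain_id, condition_with, nacl_pct, mean_w, sd_w, mean_wo, sd_wo,
            delta, None, None, None, "decrease",
        )

    if welch:
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
        df = int(np.floor(res.df))
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * sd_w**2 + (b.size - 1) * sd_wo**2) / df
        if sp2 == 0.0:
            # both groups constant; means differ (we are on the > branch)
            flags.append("degenerate")
            return ScreeningRecord(
                strain_id, condition_with, nacl_pct, mean_w, sd_w, mean_wo, sd_wo,
                delta, float("inf"), df, 0.0, "increase_p01", tuple(flags),
            )
        t = delta / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        p = float(stats.t.sf(t, df))

    if p < 0.01:
        cls = "increase_p01"
    elif p < 0.05:
        cls = "increase_p05"
    else:
        cls = "increase_ns"
    return ScreeningRecord(
        strain_id, condition_with, nacl_pct, mean_w, sd_w, mean_wo, sd_wo,
        delta, float(t), df, p, cls, tuple(flags),
    )


def screen_batch(
    records: Iterable[RespirometrySample],
    welch: bool = False,
) -> list[ScreeningRecord]:
    """Run the full screen over a mixed table of samples and blanks.

    Blanks are matched within each NaCl level.  One
    :class:`ScreeningRecord` is produced per (strain, plastic
    condition, NaCl level), ordered by strain then condition.
    """
    records = list(records)
    out: list[ScreeningRecord] = []
    nacl_levels = sorted({r.nacl_pct for r in records})
    for nacl in nacl_levels:
        level = [r for r in records if r.nacl_pct == nacl]
        blanks = [r for r in level if r.is_blank]
        samples = [r for r in level if not r.is_blank]
        if not samples:
            continue
        corrected, _ = blank_correct(samples, blanks)
        by_strain: dict[str, dict[str, list[float]]] = {}
        for s, c in zip(samples, corrected):
            by_strain.setdefault(s.strain_id, {}).setdefault(s.condition, []).append(c)
        for strain in sorted(by_strain):
            conds = by_strain[strain]
            if "none" not in conds:
                raise PairingError(f"strain {strain!r} (NaCl {nacl}%) has no without-plastic bottles")
            plastic_conds = sorted(c for c in conds if c != "none")
            if not plastic_conds:
                raise PairingError(f"strain {strain!r} (NaCl {nacl}%) has no with-plastic bottles")
            for cond in plastic_conds:
                out.append(
                    compare_conditions(
                        conds[cond], conds["none"],
                        strain_id=strain, condition_with=cond, nacl_pct=nacl, welch=welch,
                    )
                )
    return out


def count_significant(records: Iterable[ScreeningRecord], alpha: float = 0.05) -> int:
    """Number of screening records significant at ``alpha`` (one-tailed)."""
    if alpha not in (0.05, 0.01):
        raise ValueError("alpha must be 0.05 or 0.01")
    return sum(1 for r in records if r.significant(alpha))


def screening_table(records: Sequence[ScreeningRecord], bh_column: bool = False) -> pd.DataFrame:
    """Tabulate screening records; optionally add Benjamini-Hochberg q-values."""
    rows = []
    for r in records:
        rows.append(
            dict(
                strain_id=r.strain_id, condition=r.condition_with, nacl_pct=r.nacl_pct,
                mean_with=r.mean_with, sd_with=r.sd_with,
                mean_without=r.mean_without, sd_without=r.sd_without,
                delta=r.delta, t_stat=r.t_stat, df=r.df,
                p_one_tailed=r.p_one_tailed, cls=r.cls, flags=";".join(r.flags),
            )
        )
    table = pd.DataFrame(rows)
    if bh_column and len(table):
        p = table["p_one_tailed"].to_numpy(dtype=float)
        q = np.full_like(p, np.nan)
        tested = ~np.isnan(p)
        if tested.any():
            q[tested] = stats.false_discovery_control(p[tested], method="bh")
        table["q_bh"] = q
    return table


def screening_summary(records: Sequence[ScreeningRecord]) -> dict:
    """JSON-ready counts: tested, increases, significant at 0.05 / 0.01."""
    return {
        "n_records": len(records),
        "n_increase": sum(1 for r in records if r.cls != "decrease"),
        "n_p05": count_significant(records, 0.05),
        "n_p01": count_significant(records, 0.01),
    }
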