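"""Clinical concordance statistics for marked-region cohorts.

Given a cohort table with per-patient region sets marked by PET-MRI, FLAWS,
and HFO analysis, the resected set, and an Engel outcome, this module
computes:

* ``RatioChann(ev)`` — (removed − non-removed) / (removed + non-removed)
  marked channels for a marking method ``ev``; +1 means every marked
  channel was resected, −1 means none was;
* outcome dichotomization (Engel I = good, II/III = poor);
* region-level sensitivity/specificity under the marked-versus-removed
  counting rules (patients with poor outcome and non-removed marked regions
  are excluded, since their non-removed marks cannot be adjudicated);
* two-sided Fisher's exact test (probability method) and Wilcoxon rank-sum
  (exact with midranks for small samples);
* cross-modality consistency (at-least-one and complete agreement of
  marked-region sets);
* complete-removal versus outcome association tables.

Region labels are normalized by trimming, uppercasing, and stripping
parenthetical annotations; ``Normal`` denotes an empty marked set and ``/``
a modality the patient did not undergo.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MODALITIES = ("PET-MRI", "FLAWS", "HFOs")


# ---------------------------------------------------------------------------
# Cohort parsing
# ---------------------------------------------------------------------------

def parse_region_set(cell) -> set[str] | None:
    """Parse a marked-region cell.

    ``/`` (modality not performed) -> None; ``Normal`` -> empty set;
    otherwise a set of trimmed, uppercased labels with parenthetical
    suffixes such as ``(#)`` or ``(*)`` removed.
    """
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text == "/" or text == "":
        return None
    if text.upper() == "NORMAL":
        return set()
    labels = set()
    for tok in text.split(","):
        tok = re.sub(r"\(.*?\)", "", tok).strip().upper()
        if tok:
            labels.add(tok)
    return labels


@dataclass
class PatientRecord:
    """One cohort row with parsed region sets."""

    id: int
    modality_marked: dict[str, set[str] | None]
    overlapped: set[str] | None
    removed_regions: set[str] | None
    outcome: str
    chann_rem: dict[str, int] = field(default_factory=dict)
    chann_nonrem: dict[str, int] = field(default_factory=dict)
    electrodes_cover_all_imaging: bool | None = None
    hfo_completely_removed: bool | None = None


def parse_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for row in df.to_dict("records"):
        rec = PatientRecord(
            id=int(row["Patient"]),
            modality_marked={m: parse_region_set(row.get(m))
                             for m in MODALITIES},
            overlapped=parse_region_set(row.get("Overlapped")),
            removed_regions=parse_region_set(row.get("Removing")),
            outcome=str(row["Outcome"]).strip(),
        )
        if "HFOComplete" in row and not pd.isna(row["HFOComplete"]):
            rec.hfo_completely_removed = bool(row["HFOComplete"])
        if "ElectrodesCoverImaging" in row \
                and not pd.isna(row["ElectrodesCoverImaging"]):
            rec.electrodes_cover_all_imaging = \
                bool(row["ElectrodesCoverImaging"])
        for m in MODALITIES:
            key = f"ChannRem_{m}".replace("-", "")
            if key in row and not pd.isna(row[key]):
                rec.chann_rem[m] = int(row[key])
            key = f"ChannNonRem_{m}".replace("-", "")
            if key in row and not pd.isna(row[key]):
                rec.chann_nonrem[m] = int(row[key])
        records.append(rec)
    return records


def load_table1() -> pd.DataFrame:
    """Packaged 15-patient cohort fixture (the study's clinical table)."""
    with resources.files("hfoloc.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def load_table2() -> dict[str, dict[str, list[int]]]:
    """Packaged complete-removal vs outcome contingency panels."""
    with resources.files("hfoloc.data").joinpath("table2.json").open() as fh:
        return json.load(fh)["panels"]


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class RatioChannResult:
    modality: str
    n_removed: int
    n_nonremoved: int
    value: float


def ratio_chann(n_removed: int, n_nonremoved: int,
                modality: str = "") -> RatioChannResult:
    """(removed − non-removed) / (removed + non-removed) marked channels."""
    if n_removed < 0 or n_nonremoved < 0:
        raise ValueError("channel counts must be non-negative")
    if n_removed + n_nonremoved == 0:
        raise ValueError("undefined ratio: no marked channels")
    value = (n_removed - n_nonremoved) / (n_removed + n_nonremoved)
    return RatioChannResult(modality, n_removed, n_nonremoved, value)


def classify_outcome(engel_class: str) -> str:
    """Engel I -> good (seizure-free); II and III -> poor."""
    c = str(engel_class).strip().upper()
    if c == "I":
        return "good"
    if c in ("II", "III"):
        return "poor"
    raise ValueError(f"unknown Engel class {engel_class!r} "
                     "(expected I, II, or III)")


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact p (probability method).

    Sums, over all 2x2 tables with the observed margins, the hypergeometric
    probabilities no larger than that of the observed table.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("empty table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_rank_sum(group_a: Sequence[float],
                      group_b: Sequence[float]) -> float:
    """Two-sided rank-sum p; exact permutation for n_a + n_b <= 20.

    The exact branch counts, over all C(N, n_a) assignments of the pooled
    midranks, those whose rank sum deviates from its mean at least as much
    as observed (the permutation distribution of the rank sum is symmetric,
    with or without ties). Larger samples use the normal approximation with
    tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = a.size, b.size
    if n + m > 20:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic")[1])
    ranks = _midranks(np.concatenate([a, b]))
    # doubled midranks are integers -> exact distribution by subset-sum DP
    r2 = np.round(ranks * 2).astype(int)
    w_obs = int(r2[:n].sum())
    mu2 = n * (n + m + 1)              # doubled mean of the rank sum
    dev = abs(w_obs - mu2)
    max_sum = int(r2.sum())
    # dp[k, s] = number of k-subsets of the ranks with doubled sum s
    dp = np.zeros((n + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n, 0, -1):
            dp[k, r:] += dp[k - 1, :max_sum + 1 - r]
    counts = dp[n]
    sums = np.arange(max_sum + 1)
    extreme = counts[np.abs(sums - mu2) >= dev - 1e-9].sum()
    return float(extreme / counts.sum())


# ---------------------------------------------------------------------------
# Consistency and confusion
# ---------------------------------------------------------------------------

def consistency(cohort: pd.DataFrame | list[PatientRecord],
                modality_a: str, modality_b: str) -> dict:
    """Cross-modality agreement of marked-region sets.

    Rows lacking either modality (``/``) are excluded from ``n_evaluable``;
    ``Normal`` counts as an evaluable empty set. At-least-one = non-empty
    intersection under exact label matching; complete = set equality.
    """
    records = cohort if isinstance(cohort, list) else parse_cohort(cohort)
    sets = [(r.modality_marked.get(modality_a),
             r.modality_marked.get(modality_b)) for r in records]
    if all(sa is None for sa, _ in sets):
        raise ValueError(f"modality {modality_a!r} absent from all rows")
    if all(sb is None for _, sb in sets):
        raise ValueError(f"modality {modality_b!r} absent from all rows")
    evaluable = [(sa, sb) for sa, sb in sets
                 if sa is not None and sb is not None]
    n = len(evaluable)
    n_any = sum(1 for sa, sb in evaluable if sa & sb)
    n_complete = sum(1 for sa, sb in evaluable if sa == sb)
    return {
        "n_evaluable": n,
        "n_at_least_one": n_any,
        "pct_at_least_one": 100.0 * n_any / n if n else float("nan"),
        "n_complete": n_complete,
        "pct_complete": 100.0 * n_complete / n if n else float("nan"),
    }


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else \
            float("nan")

    @property
    def specificity(self) -> float:
        # standard TN / (TN + FP)
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else \
            float("nan")


def confusion_counts(cohort: pd.DataFrame | list[PatientRecord],
                     modality: str) -> ConfusionCounts:
    """Region-level confusion counts for one marking method.

    Good-outcome patients: each marked-and-removed region is a true
    positive, each marked-but-not-removed region a false positive, and the
    unmarked remainder contributes one true-negative token per patient.
    Poor-outcome patients: marked-and-removed regions are true positives
    and the residual EZ contributes one false-negative token per patient;
    poor-outcome patients with non-removed marked regions are excluded
    (those marks cannot be adjudicated). Rows lacking the modality or
    removal data are excluded with a log entry.
    """
    records = cohort if isinstance(cohort, list) else parse_cohort(cohort)
    tp = fp = tn = fn = excluded = 0
    for rec in records:
        marked = rec.modality_marked.get(modality)
        removed = rec.removed_regions
        if marked is None or removed is None:
            logger.info("patient %s lacks %s or removal data; excluded",
                        rec.id, modality)
            excluded += 1
            continue
        good = classify_outcome(rec.outcome) == "good"
        n_rem = len(marked & removed)
        n_nonrem = len(marked - removed)
        if good:
            tp += n_rem
            fp += n_nonrem
            tn += 1
        else:
            if n_nonrem > 0:
                excluded += 1
                continue
            tp += n_rem
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, n_excluded=excluded)


def multimodal_flag(patient: PatientRecord) -> bool:
    """Electrodes covered all imaging-suspicious areas AND the HFO-marked
    areas were completely removed."""
    if patient.electrodes_cover_all_imaging is None \
            or patient.hfo_completely_removed is None:
        raise ValueError(
            f"patient {patient.id}: multimodal flag needs both "
            "electrodes_cover_all_imaging and hfo_completely_removed")
    return bool(patient.electrodes_cover_all_imaging
                and patient.hfo_completely_removed)


# ---------------------------------------------------------------------------
# Outcome association
# ---------------------------------------------------------------------------

def _condition_value(rec: PatientRecord, condition: str) -> bool | None:
    def complete(modality: str) -> bool | None:
        marked = rec.modality_marked.get(modality)
        if marked is None or rec.removed_regions is None:
            return None
        return marked <= rec.removed_regions

    if condition == "pet_complete":
        return complete("PET-MRI")
    if condition == "flaws_complete":
        return complete("FLAWS")
    if condition == "hfo_complete":
        if rec.hfo_completely_removed is not None:
            return rec.hfo_completely_removed
        return complete("HFOs")
    if condition == "multimodal":
        try:
            return multimodal_flag(rec)
        except ValueError:
            return None
    raise ValueError(f"unknown condition {condition!r}")


def outcome_association(cohort: pd.DataFrame | list[PatientRecord],
                        condition: str) -> tuple[np.ndarray, float]:
    """2x2 (condition yes/no × seizure-free/not) table and Fisher p.

    Rows where the condition cannot be computed are dropped with a log
    entry; an error is raised if nothing remains.
    """
    records = cohort if isinstance(cohort, list) else parse_cohort(cohort)
    table = np.zeros((2, 2), dtype=int)
    n_used = 0
    for rec in records:
        val = _condition_value(rec, condition)
        if val is None:
            logger.info("patient %s: condition %s not computable; dropped",
                        rec.id, condition)
            continue
        good = classify_outcome(rec.outcome) == "good"
        table[0 if val else 1, 0 if good else 1] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError(f"condition {condition} computable for no row")
    return table, fisher_exact_two_sided(table)


def association_from_counts(panel: dict[str, list[int]]
                            ) -> tuple[np.ndarray, float]:
    """Association p-value from a stored contingency panel
    (``{"yes": [sf, nsf], "no": [sf, nsf]}``)."""
    table = np.array([panel["yes"], panel["no"]], dtype=int)
    return table, fisher_exact_two_sided(table)


def seizure_free_percentage(cohort: pd.DataFrame | list[PatientRecord]
                            ) -> float:
    """Percent of patients with Engel class I outcome."""
    records = cohort if isinstance(cohort, list) else parse_cohort(cohort)
    if not records:
        raise ValueError("empty cohort")
    n_good = sum(1 for r in records
                 if classify_outcome(r.outcome) == "good")
    return 100.0 * n_good / len(records)
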