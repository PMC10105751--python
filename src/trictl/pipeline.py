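"""From raw longitudinal records to labeled learning examples.

The prognostic pipeline consolidates irregular clinical evaluations into
*snapshots* (constrained agglomerative clustering of visit dates, 100-day
cut), computes ALSFRS-R functional scores and the MITOS stage, flags the
critical endpoints C1-C5, assigns each snapshot an *Evolution* label for a
k-day horizon (situations A-E), and groups consecutive snapshots into
windows of length ``min(L, nP)`` that become the learning examples.

Endpoints (first evaluation meeting the rule defines the critical date):

- C1 need for non-invasive ventilation: Q12 <= 3
- C2 need for an auxiliary communication device: Q1 <= 1
- C3 need for percutaneous endoscopic gastrostomy: Q3 <= 2
- C4 need for a caregiver: Q5 <= 1 or Q6 <= 1
- C5 need for a wheelchair: Q8 <= 1
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .data_model import EvaluationRecord, Feature, ThreeWayDataset

__all__ = [
    "EndpointRule",
    "ENDPOINTS",
    "Snapshot",
    "LearningExample",
    "functional_scores",
    "mitos_stage",
    "build_snapshots",
    "flag_critical",
    "label_evolution",
    "group_windows",
    "make_learning_examples",
    "examples_to_tensor",
    "QUESTIONS",
    "SNAPSHOT_FEATURES",
]

QUESTIONS = tuple(f"Q{i}" for i in range(1, 13))

#: Consolidated per-snapshot feature vector (order fixed for tensors).
SNAPSHOT_FEATURES = QUESTIONS + (
    "FVC",
    "ALSFRS-R",
    "ALSFRSb",
    "ALSFRSsUL",
    "ALSFRSsLL",
    "R",
    "MITOS",
)


@dataclass(frozen=True)
class EndpointRule:
    """A critical endpoint: an id (C1..C5) and a predicate on question scores."""

    id: str
    questions: tuple
    predicate: Callable[[Mapping[str, float]], bool]

    def __call__(self, q: Mapping[str, float]) -> bool:
        for name in self.questions:
            if q.get(name) is None:
                raise ValueError(f"endpoint {self.id} needs {name}, which is missing")
        return self.predicate(q)


ENDPOINTS: dict[str, EndpointRule] = {
    "C1": EndpointRule("C1", ("Q12",), lambda q: q["Q12"] <= 3),
    "C2": EndpointRule("C2", ("Q1",), lambda q: q["Q1"] <= 1),
    "C3": EndpointRule("C3", ("Q3",), lambda q: q["Q3"] <= 2),
    "C4": EndpointRule("C4", ("Q5", "Q6"), lambda q: q["Q5"] <= 1 or q["Q6"] <= 1),
    "C5": EndpointRule("C5", ("Q8",), lambda q: q["Q8"] <= 1),
}


@dataclass
class Snapshot:
    """A consolidated picture of one patient's condition around one date."""

    patient_id: str
    snapshot_date: date
    member_records: list = field(default_factory=list)
    feature_vector: dict = field(default_factory=dict)
    critical_flags: dict = field(default_factory=dict)


@dataclass
class LearningExample:
    """A window of <= L consecutive snapshots labeled for one (endpoint, k) task."""

    patient_id: str
    window: list  # ordered Snapshots
    endpoint: str
    horizon_k: int
    evolution: str  # "Y" | "N"
    situation: str  # "A".."E"
    eligible: bool = True


def functional_scores(q: Mapping[str, float]) -> dict:
    """ALSFRS-R total and sub-scores from the 12 question scores.

    total = Q1..Q12; bulbar ALSFRSb = Q1+Q2+Q3; upper-limb ALSFRSsUL =
    Q4+Q5+Q6; lower-limb ALSFRSsLL = Q7+Q8+Q9; respiratory R = Q10+Q11+Q12.
    """
    vals = {}
    for name in QUESTIONS:
        v = q.get(name)
        if v is None or not (0 <= v <= 4) or v != int(v):
            raise ValueError(f"question {name}={v!r} must be an integer in 0..4")
        vals[name] = int(v)
    return {
        "ALSFRS-R": sum(vals.values()),
        "ALSFRSb": vals["Q1"] + vals["Q2"] + vals["Q3"],
        "ALSFRSsUL": vals["Q4"] + vals["Q5"] + vals["Q6"],
        "ALSFRSsLL": vals["Q7"] + vals["Q8"] + vals["Q9"],
        "R": vals["Q10"] + vals["Q11"] + vals["Q12"],
    }


def _load_default_mitos_rules() -> dict:
    ref = importlib.resources.files("trictl").joinpath("mitos_rules.yaml")
    return yaml.safe_load(ref.read_text())


_DEFAULT_MITOS = None


def mitos_stage(q: Mapping[str, float], death_flag: bool = False, rules: dict | None = None) -> int:
    """MITOS disease stage: number of compromised functional domains, 5 = death.

    Domain triggers follow the published staging rules (movement, swallowing,
    communicating, breathing), read from ``mitos_rules.yaml`` so they can be
    corrected without code changes.
    """
    global _DEFAULT_MITOS
    if death_flag:
        return 5
    if rules is None:
        if _DEFAULT_MITOS is None:
            _DEFAULT_MITOS = _load_default_mitos_rules()
        rules = _DEFAULT_MITOS
    stage = 0
    for domain, spec in rules.items():
        if "any_of" in spec:
            hit = any(q[c["question"]] <= c["max"] for c in spec["any_of"])
        else:
            hit = all(q[c["question"]] <= c["max"] for c in spec["all_of"])
        stage += int(hit)
    return stage


def _record_critical_flags(rec: EvaluationRecord) -> dict:
    """Endpoint flags computable from one record (None when questions absent)."""
    flags = {}
    for eid, rule in ENDPOINTS.items():
        if all(rec.measurements.get(qn) is not None for qn in rule.questions):
            flags[eid] = rule.predicate(rec.measurements)
        else:
            flags[eid] = None
    return flags


def build_snapshots(
    records: Sequence[EvaluationRecord],
    cut_days: int = 100,
    death_dates: Mapping[str, date] | None = None,
) -> list[Snapshot]:
    """Group each patient's evaluations into snapshots.

    Complete-linkage agglomerative clustering on evaluation dates with two
    cannot-link constraints: records of the same test never share a snapshot,
    and all members of a snapshot must agree on every endpoint's critical
    status.  Merging stops when the closest admissible pair of groups is more
    than ``cut_days`` apart, so the within-snapshot date span never exceeds
    the cut.  The snapshot date is the median member date (even-sized groups
    take the earlier of the two middle dates).
    """
    death_dates = death_dates or {}
    by_patient: dict[str, list[EvaluationRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    snapshots: list[Snapshot] = []
    for pid in sorted(by_patient):
        recs = sorted(by_patient[pid], key=lambda r: (r.date, r.test_name))
        flags = [_record_critical_flags(r) for r in recs]
        clusters = [[i] for i in range(len(recs))]

        def admissible(c1, c2):
            tests1 = {recs[i].test_name for i in c1}
            if tests1 & {recs[i].test_name for i in c2}:
                return False
            for eid in ENDPOINTS:
                vals = {flags[i][eid] for i in c1 + c2} - {None}
                if len(vals) > 1:
                    return False
            return True

        def distance(c1, c2):  # complete linkage on dates, in days
            return max(abs((recs[i].date - recs[j].date).days) for i in c1 for j in c2)

        while len(clusters) > 1:
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    if not admissible(clusters[a], clusters[b]):
                        continue
                    d = distance(clusters[a], clusters[b])
                    if d <= cut_days and (best is None or d < best[0]):
                        best = (d, a, b)
            if best is None:
                break
            _, a, b = best
            clusters[a] = sorted(clusters[a] + clusters[b])
            del clusters[b]

        for cl in clusters:
            members = [recs[i] for i in cl]
            dates = sorted(m.date for m in members)
            median_date = dates[(len(dates) - 1) // 2]  # earlier-of-middle-two
            feats: dict = {}
            for m in sorted(members, key=lambda r: r.date):  # most-recent-wins
                feats.update({k: v for k, v in m.measurements.items() if v is not None})
            if all(feats.get(qn) is not None for qn in QUESTIONS):
                feats.update(functional_scores(feats))
                died = pid in death_dates and death_dates[pid] <= median_date
                feats["MITOS"] = mitos_stage(feats, death_flag=died)
            crit = {}
            for eid, rule in ENDPOINTS.items():
                if all(feats.get(qn) is not None for qn in rule.questions):
                    crit[eid] = rule.predicate(feats)
                else:
                    crit[eid] = None
            snapshots.append(Snapshot(pid, median_date, members, feats, crit))
    snapshots.sort(key=lambda s: (s.patient_id, s.snapshot_date))
    return snapshots


def flag_critical(snapshot: Snapshot, rule: EndpointRule) -> bool:
    """Apply an endpoint rule to a snapshot's consolidated features."""
    return rule(snapshot.feature_vector)


def label_evolution(
    snapshots: Sequence[Snapshot],
    rule: EndpointRule,
    k: int,
    critical_date: date | None = None,
    last_info_date: date | None = None,
) -> list[tuple[str | None, bool, str]]:
    """Per-snapshot Evolution label for a k-day horizon.

    With ``i`` the snapshot date and the critical date the first date the
    endpoint rule fires (or a recorded event date):

    - A: critical date in ``(i, i + k]``            -> (Y, eligible)
    - B: critical date after ``i + k``              -> (N, eligible)
    - C: never critical, some snapshot after i + k  -> (N, eligible)
    - D: no status information after ``i + k``      -> ineligible
    - E: the snapshot itself is critical (or dated on/after the critical
      date)                                         -> ineligible
    """
    snaps = sorted(snapshots, key=lambda s: s.snapshot_date)
    if critical_date is None:
        for s in snaps:
            if flag_critical(s, rule):
                critical_date = s.snapshot_date
                break
    if last_info_date is None and snaps:
        last_info_date = snaps[-1].snapshot_date
    out = []
    for s in snapshots:
        i = s.snapshot_date
        if flag_critical(s, rule) or (critical_date is not None and i >= critical_date):
            out.append((None, False, "E"))
        elif critical_date is not None:
            if i < critical_date <= i + timedelta(days=k):
                out.append(("Y", True, "A"))
            else:  # critical_date > i + k
                out.append(("N", True, "B"))
        else:
            if last_info_date is not None and last_info_date > i + timedelta(days=k):
                out.append(("N", True, "C"))
            else:
                out.append((None, False, "D"))
    return out


def group_windows(
    snapshots: Sequence[Snapshot],
    labels: Sequence[tuple[str | None, bool, str]],
    rule: EndpointRule,
    k: int,
    L: int,
) -> list[LearningExample]:
    """Sliding windows of consecutive snapshots, one learning example each.

    Only eligible (non-critical) snapshots enter windows.  With ``nP`` the
    number of such snapshots for the patient, windows have length
    ``min(L, nP)`` and stride 1, so the patient contributes
    ``max(nP - L + 1, 1)`` examples; the label is the LAST snapshot's.
    """
    pairs = [
        (s, lab)
        for s, lab in zip(snapshots, labels)
        if lab[1]  # eligible only
    ]
    pairs.sort(key=lambda p: p[0].snapshot_date)
    nP = len(pairs)
    if nP == 0:
        return []
    w = min(L, nP)
    out = []
    for start in range(nP - w + 1):
        window = pairs[start : start + w]
        last_label = window[-1][1]
        out.append(
            LearningExample(
                patient_id=window[0][0].patient_id,
                window=[s for s, _ in window],
                endpoint=rule.id,
                horizon_k=k,
                evolution=last_label[0],
                situation=last_label[2],
            )
        )
    return out


def make_learning_examples(
    records: Sequence[EvaluationRecord],
    endpoint: str,
    k: int,
    L: int,
    cut_days: int = 100,
    critical_dates: Mapping[str, date] | None = None,
) -> list[LearningExample]:
    """End-to-end: records -> snapshots -> Evolution labels -> windows."""
    rule = ENDPOINTS[endpoint]
    snaps = build_snapshots(records, cut_days=cut_days)
    by_patient: dict[str, list[Snapshot]] = {}
    for s in snaps:
        by_patient.setdefault(s.patient_id, []).append(s)
    examples: list[LearningExample] = []
    for pid in sorted(by_patient):
        plist = by_patient[pid]
        cdate = critical_dates.get(pid) if critical_dates else None
        labels = label_evolution(plist, rule, k, critical_date=cdate)
        examples.extend(group_windows(plist, labels, rule, k, L))
    return examples


def examples_to_tensor(
    examples: Sequence[LearningExample],
    L: int,
    feature_names: Sequence[str] = SNAPSHOT_FEATURES,
) -> ThreeWayDataset:
    """Stack learning-example windows into a three-way tensor.

    Objects are examples, contexts are the L window positions (windows are
    anchored to the END: shorter windows leave their leading contexts
    missing), features are the consolidated snapshot features.  Feature
    values the snapshots lack stay masked; the miner skips masked cells.
    """
    n, m = len(examples), len(feature_names)
    values = np.zeros((n, m, L))
    mask = np.ones((n, m, L), dtype=bool)
    for i, ex in enumerate(examples):
        offset = L - len(ex.window)
        for pos, snap in enumerate(ex.window):
            for j, fname in enumerate(feature_names):
                v = snap.feature_vector.get(fname)
                if v is not None:
                    values[i, j, offset + pos] = float(v)
                    mask[i, j, offset + pos] = False
    features = [Feature(name, "ordinal" if name.startswith("Q") else "numeric") for name in feature_names]
    objects = [f"ex{i}" for i in range(n)]
    return ThreeWayDataset(objects, features, list(range(L)), values, mask)
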