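"""Synthetic data: planted-tricluster tensors and ALS-like cohorts.

Two generators stand in for private clinical data.  The tensor generator
plants time-contiguous coherent blocks (constant, scaling or shifting) in
continuous background noise, so spurious exact ratio coherence has
probability zero and recovery can be scored against the ground truth by
cell-level Jaccard.  The cohort generator emits irregular-visit evaluation
records with monotonically declining ALSFRS-R question scores driven by
latent linear trajectories; the latent trajectory (not the noisy
observations) defines the true endpoint-crossing dates, so labeling tests
can separate observation error from labeling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .data_model import EvaluationRecord, Feature, ThreeWayDataset
from .mining import Tricluster
from .pipeline import ENDPOINTS, QUESTIONS

__all__ = [
    "PlantedBlock",
    "PlantedGroundTruth",
    "CohortSpec",
    "plant_tensor",
    "simulate_cohort",
    "recovery_score",
    "match_triclusters",
]


@dataclass(frozen=True)
class PlantedBlock:
    """One planted tricluster: index sets, pattern kind and base values."""

    objects: tuple
    features: tuple
    contexts: tuple  # must be a consecutive run
    kind: str = "constant"  # constant | scaling | shifting
    base: float = 2.0

    def __post_init__(self):
        ks = sorted(self.contexts)
        if ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("planted context set must be a consecutive run")
        if self.kind not in ("constant", "scaling", "shifting"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")

    def as_tricluster(self) -> Tricluster:
        return Tricluster(tuple(self.objects), tuple(self.features), tuple(self.contexts))


@dataclass
class PlantedGroundTruth:
    """Planted blocks + noise model; sufficient to rebuild the clean tensor."""

    blocks: list
    noise_sd: float
    seed: int
    background: tuple = (1.0, 3.0)  # uniform background range (positive)


def plant_tensor(shape: tuple, ground_truth: PlantedGroundTruth) -> ThreeWayDataset:
    """Generate a tensor of background noise with the planted blocks overwritten.

    Background cells are i.i.d. uniform on ``ground_truth.background``; each
    planted cell is its pattern value plus Gaussian noise of sd
    ``noise_sd``.  Deterministic for a fixed seed.  Overlapping blocks are
    allowed (later blocks overwrite); out-of-bounds blocks are an error.
    """
    n, m, p = shape
    rng = np.random.default_rng(ground_truth.seed)
    lo, hi = ground_truth.background
    values = rng.uniform(lo, hi, size=shape)
    for block in ground_truth.blocks:
        if max(block.objects) >= n or max(block.features) >= m or max(block.contexts) >= p:
            raise ValueError(f"planted block {block} exceeds tensor bounds {shape}")
        # deterministic per-feature / per-object factors derived from the block rng
        brng = np.random.default_rng((ground_truth.seed, hash(block.objects) & 0x7FFFFFFF))
        fvals = block.base * brng.uniform(0.8, 1.2, size=len(block.features))
        ofac = brng.uniform(0.7, 1.4, size=len(block.objects))
        for a, i in enumerate(sorted(block.objects)):
            for b, j in enumerate(sorted(block.features)):
                for k in sorted(block.contexts):
                    if block.kind == "constant":
                        v = fvals[b]
                    elif block.kind == "scaling":
                        v = fvals[b] * ofac[a]
                    else:  # shifting
                        v = fvals[b] + ofac[a]
                    values[i, j, k] = v + rng.normal(0.0, ground_truth.noise_sd)
    values = np.maximum(values, 1e-6)  # keep the ratio model defined
    features = [Feature(f"y{j}", "numeric") for j in range(m)]
    mask = np.zeros(shape, dtype=bool)
    return ThreeWayDataset([f"x{i}" for i in range(n)], features, list(range(p)), values, mask)


@dataclass
class CohortSpec:
    """Study conditions for the simulated ALS-like cohort.

    Defaults describe a regular specialist follow-up: visits every ~90 days
    over ~3 years, ALSFRS-R questions starting near the 4-point ceiling and
    declining linearly at a per-question monthly rate scaled by the
    patient's progressor class (slow / neutral / fast).
    """

    n_patients: int = 100
    visit_interval_days: tuple = (60, 120)  # uniform range between visits
    horizon_days: int = 1000
    baseline_range: tuple = (3.6, 4.4)  # latent starting score per question (clipped at 4)
    monthly_decline: float = 0.12  # latent points per 30 days per question
    decline_jitter: float = 0.35  # multiplicative per-question jitter
    progressor_mix: tuple = (0.3, 0.4, 0.3)  # slow, neutral, fast weights
    progressor_rates: tuple = (0.3, 1.0, 2.6)  # rate multipliers per class
    fvc_baseline: float = 95.0
    fvc_monthly_decline: float = 1.2
    missing_rate: float = 0.1  # chance an FVC record is skipped
    start_date: date = date(2020, 1, 1)
    seed: int = 0


def _first_crossing_day(q0: float, rate_per_day: float, threshold: int, horizon: int):
    """First day the rounded-and-clipped latent score falls to <= threshold."""
    if rate_per_day <= 0:
        return None
    # score(t) = clip(round(q0 - rate*t)) <= threshold  iff  latent < threshold + 0.5
    t = (q0 - (threshold + 0.5)) / rate_per_day
    day = max(0, int(np.ceil(t)))
    if q0 - rate_per_day * day >= threshold + 0.5:
        day += 1
    return day if day <= horizon else None


def simulate_cohort(spec: CohortSpec):
    """Simulate an irregular-visit cohort with known endpoint-crossing dates.

    Returns ``(records, truth)`` where ``truth`` maps patient_id to a dict
    with the progressor class and, per endpoint C1..C5, the true first
    crossing date (or None) computed from the latent trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[EvaluationRecord] = []
    truth: dict = {}
    endpoint_thresholds = {
        "C1": [("Q12", 3)],
        "C2": [("Q1", 1)],
        "C3": [("Q3", 2)],
        "C4": [("Q5", 1), ("Q6", 1)],
        "C5": [("Q8", 1)],
    }
    classes = ("slow", "neutral", "fast")
    for pi in range(spec.n_patients):
        pid = f"P{pi:04d}"
        cls_idx = rng.choice(3, p=np.asarray(spec.progressor_mix) / sum(spec.progressor_mix))
        mult = spec.progressor_rates[cls_idx]
        q0 = rng.uniform(*spec.baseline_range, size=12)
        jitter = rng.uniform(1 - spec.decline_jitter, 1 + spec.decline_jitter, size=12)
        rate_day = spec.monthly_decline * mult * jitter / 30.0  # per question
        # true crossing dates from the latent trajectories
        crossings = {}
        for eid, qs in endpoint_thresholds.items():
            days = [
                _first_crossing_day(q0[int(qn[1:]) - 1], rate_day[int(qn[1:]) - 1], thr, spec.horizon_days)
                for qn, thr in qs
            ]
            days = [d for d in days if d is not None]
            crossings[eid] = (
                spec.start_date + timedelta(days=min(days)) if days else None
            )
        truth[pid] = {"class": classes[cls_idx], "crossings": crossings}
        # visits
        t = int(rng.integers(0, 15))
        while t <= spec.horizon_days:
            d = spec.start_date + timedelta(days=t)
            latent = q0 - rate_day * t
            scores = np.clip(np.round(latent), 0, 4).astype(int)
            records.append(
                EvaluationRecord(
                    pid, d, "ALSFRS-R", {qn: int(s) for qn, s in zip(QUESTIONS, scores)}
                )
            )
            if rng.random() >= spec.missing_rate:
                fvc = spec.fvc_baseline - spec.fvc_monthly_decline * mult * t / 30.0
                fvc += rng.normal(0, 1.5)
                records.append(EvaluationRecord(pid, d, "FVC", {"FVC": max(fvc, 10.0)}))
            t += int(rng.integers(*spec.visit_interval_days))
    return records, truth


def recovery_score(found: Tricluster, planted: Tricluster) -> float:
    """Cell-level Jaccard between two triclusters in the same tensor frame."""
    if found.n_cells() == 0 or planted.n_cells() == 0:
        raise ValueError("empty tricluster has no recovery score")
    a, b = found.cells(), planted.cells()
    return len(a & b) / len(a | b)


def match_triclusters(found: list, planted: list) -> list[float]:
    """Greedy best-match Jaccard of each planted block against the found set.

    Pairs are assigned greedily by descending Jaccard (each found tricluster
    used at most once); planted blocks left unmatched score 0.
    """
    if not planted:
        return []
    pairs = sorted(
        (
            (recovery_score(f, p.as_tricluster() if isinstance(p, PlantedBlock) else p), fi, pi)
            for fi, f in enumerate(found)
            for pi, p in enumerate(planted)
        ),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    used_f: set = set()
    scores = {pi: 0.0 for pi in range(len(planted))}
    matched: set = set()
    for s, fi, pi in pairs:
        if fi in used_f or pi in matched:
            continue
        used_f.add(fi)
        matched.add(pi)
        scores[pi] = s
    return [scores[pi] for pi in range(len(planted))]
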