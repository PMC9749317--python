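"""Patient-disjoint train/validation/test splitting.

Records are drawn into validation and test by whole patients, so no
patient's recordings can leak across partitions; target record counts
(default 50 validation / 100 test) are hit exactly by a randomized
first-fit over patient permutations, retried with fresh permutations
until the counts land.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRAIN, VALIDATION, TEST = "train", "validation", "test"


@dataclass
class SplitAssignment:
    """record_id -> partition, with the roster it was built from."""

    assignment: dict
    roster: pd.DataFrame    # record_id, patient_id, label

    def records(self, part: str) -> list:
        return [r for r, p in self.assignment.items() if p == part]

    def patients(self, part: str) -> set:
        recs = set(self.records(part))
        sub = self.roster[self.roster["record_id"].isin(recs)]
        return set(sub["patient_id"])

    def counts(self) -> dict:
        out = {TRAIN: 0, VALIDATION: 0, TEST: 0}
        for p in self.assignment.values():
            out[p] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        df = self.roster.copy()
        df["partition"] = df["record_id"].map(self.assignment)
        return df


def _normalize_roster(roster) -> pd.DataFrame:
    if isinstance(roster, pd.DataFrame):
        df = roster[["record_id", "patient_id", "label"]].copy()
    else:  # mapping record_id -> (patient_id, label)
        df = pd.DataFrame(
            [(r, p, l) for r, (p, l) in roster.items()],
            columns=["record_id", "patient_id", "label"],
        )
    if df["record_id"].duplicated().any():
        raise ValueError("duplicate record ids in roster")
    two = df.groupby("patient_id")["label"].nunique()
    if (two > 1).any():
        bad = two[two > 1].index.tolist()
        raise ValueError(f"patients with conflicting labels: {bad}")
    return df


def _first_fit(order, sizes: dict, target: int) -> list | None:
    """Accumulate whole patients until the record count hits ``target``
    exactly; patients that would overshoot are skipped."""
    chosen, total = [], 0
    for p in order:
        c = sizes[p]
        if total + c <= target:
            chosen.append(p)
            total += c
            if total == target:
                return chosen
    return None


def split_by_patient(roster, target_val_n: int = 50, target_test_n: int = 100,
                     seed: int = 0, max_retries: int = 200) -> SplitAssignment:
    """Assign records to train/validation/test with patient disjointness.

    ``roster`` is a DataFrame (record_id, patient_id, label) or a mapping
    record_id -> (patient_id, label).  Validation is filled to exactly
    ``target_val_n`` records by whole patients, then test to
    ``target_test_n`` from the remainder; everything else is train.
    Deterministic under ``seed``.  Raises if no patient combination
    achieves the exact counts within the retry budget, reporting the
    nearest achievable counts found.
    """
    df = _normalize_roster(roster)
    n_total = len(df)
    if n_total <= target_val_n + target_test_n:
        raise ValueError(
            f"roster has {n_total} records; needs more than "
            f"{target_val_n + target_test_n}"
        )
    sizes = df.groupby("patient_id").size().to_dict()
    patients = sorted(sizes)
    rng = np.random.default_rng(seed)
    best = (None, None, -1)
    for _ in range(max_retries):
        order = list(rng.permutation(patients))
        val = _first_fit(order, sizes, target_val_n)
        if val is None:
            continue
        remaining = [p for p in order if p not in set(val)]
        test = _first_fit(remaining, sizes, target_test_n)
        if test is None:
            achieved = sum(sizes[p] for p in val)
            if achieved > best[2]:
                best = (val, None, achieved)
            continue
        val_set, test_set = set(val), set(test)
        assignment = {}
        for rec, pat in zip(df["record_id"], df["patient_id"]):
            if pat in val_set:
                assignment[rec] = VALIDATION
            elif pat in test_set:
                assignment[rec] = TEST
            else:
                assignment[rec] = TRAIN
        return SplitAssignment(assignment=assignment, roster=df)
    raise ValueError(
        f"could not reach exact counts val={target_val_n}, test={target_test_n} "
        f"within {max_retries} retries; consider targets near the achievable "
        f"patient-group sums (record counts per patient: "
        f"min {min(sizes.values())}, max {max(sizes.values())})"
    )
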