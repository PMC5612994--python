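"""Cross-validation split and label-permutation generators.

Splits are deterministic enumerations keyed by (run, condition) pairs:
leave-two-identities-out for familiarity decoding (test identities never
seen in training) and leave-one-run-out for identity decoding.  Label
permutations provide the per-subject null distributions: the exhaustive
balanced familiarity relabelings (35 for 8 conditions, after complement
deduplication) and seeded within-run identity shuffles.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Split",
    "LabelPermutation",
    "leave_two_identities_out_splits",
    "leave_one_run_out_splits",
    "enumerate_familiarity_permutations",
    "identity_permutations_within_run",
    "write_splits_jsonl",
]

Key = tuple[int, str]  # (run label, condition label)


@dataclass(frozen=True)
class Split:
    train: frozenset[Key]
    test: frozenset[Key]
    scheme: str  # "l2io" | "loro"

    def __post_init__(self) -> None:
        if self.train & self.test:
            raise ValueError("train and test sets overlap")
        if not self.test:
            raise ValueError("test set is empty")


@dataclass(frozen=True)
class LabelPermutation:
    """Either a global condition->class relabeling or per-run identity shuffles."""

    kind: str  # "familiarity" | "identity"
    canonical_id: int
    global_map: tuple[tuple[str, str], ...] | None = None  # condition -> class
    per_run: tuple[tuple[int, tuple[tuple[str, str], ...]], ...] | None = None

    def familiarity_map(self) -> dict[str, str]:
        if self.global_map is None:
            raise ValueError("not a familiarity permutation")
        return dict(self.global_map)

    def run_maps(self) -> dict[int, dict[str, str]]:
        if self.per_run is None:
            raise ValueError("not an identity permutation")
        return {run: dict(m) for run, m in self.per_run}


def leave_two_identities_out_splits(
    familiar: list[str], unfamiliar: list[str], runs: list[int]
) -> list[Split]:
    """One split per (familiar, unfamiliar) identity pair.

    The pair's betas from every run form the test set; all runs of the
    remaining identities form the training set, so no test identity's
    data appear in training.  |familiar| x |unfamiliar| splits.
    """
    if set(familiar) & set(unfamiliar):
        raise ValueError("an identity appears in both familiarity classes")
    if len(familiar) < 2 or len(unfamiliar) < 2:
        raise ValueError("need at least 2 identities per class")
    splits = []
    for f, u in itertools.product(familiar, unfamiliar):
        test = frozenset((r, c) for r in runs for c in (f, u))
        train = frozenset(
            (r, c) for r in runs for c in familiar + unfamiliar if c not in (f, u)
        )
        splits.append(Split(train, test, "l2io"))
    return splits


def leave_one_run_out_splits(runs: list[int], conditions: list[str]) -> list[Split]:
    """One split per run: that run's conditions test, all other runs train."""
    if len(runs) < 2:
        raise ValueError("leave-one-run-out requires at least 2 runs")
    splits = []
    for held in runs:
        test = frozenset((held, c) for c in conditions)
        train = frozenset((r, c) for r in runs if r != held for c in conditions)
        splits.append(Split(train, test, "loro"))
    return splits


def enumerate_familiarity_permutations(
    identities: list[str], classes: tuple[str, str] = ("familiar", "unfamiliar")
) -> list[LabelPermutation]:
    """All balanced binary relabelings of the conditions, up to complement.

    A relabeling and its complement yield identical accuracy for a
    symmetric binary classifier, so representatives are chosen with the
    first identity always in the first class: C(2k, k)/2 permutations,
    including the veridical labeling's class.  35 for 8 identities.
    """
    n = len(identities)
    if n % 2 != 0:
        raise ValueError("familiarity permutations require an even number of identities")
    k = n // 2
    first, rest = identities[0], list(identities[1:])
    perms = []
    for i, combo in enumerate(itertools.combinations(rest, k - 1)):
        pos = {first, *combo}
        mapping = tuple((c, classes[0] if c in pos else classes[1]) for c in identities)
        perms.append(LabelPermutation("familiarity", canonical_id=i, global_map=mapping))
    return perms


def identity_permutations_within_run(
    conditions: list[str], runs: list[int], n_perms: int = 20, seed: int = 0
) -> list[LabelPermutation]:
    """Seeded within-run shuffles of the identity labels, one list per draw."""
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_perms):
        per_run = []
        for r in runs:
            shuffled = list(rng.permutation(conditions))
            per_run.append((r, tuple(zip(conditions, shuffled))))
        out.append(LabelPermutation("identity", canonical_id=i, per_run=tuple(per_run)))
    return out


def write_splits_jsonl(splits: list[Split], path) -> None:
    """Serialize splits to JSON lines for audit."""
    with open(path, "w") as fh:
        for s in splits:
            fh.write(
                json.dumps(
                    {
                        "scheme": s.scheme,
                        "train": sorted(map(list, s.train)),
                        "test": sorted(map(list, s.test)),
                    }
                )
                + "\n"
            )
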