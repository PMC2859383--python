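"""Permuted discriminant function analysis (pDFA).

When notes from the same animal enter a group-level DFA (sex, dominance,
treatment), the nested individual effect inflates apparent group
discrimination: enough idiosyncratic structure exists in any set of animals
that *some* acoustic dimension separates two arbitrary subsets of them. The
pDFA therefore compares the observed cross-validated percent correct to a
null distribution obtained by permuting the group label **of each
individual** (never of single notes), preserving group sizes; all notes of
an animal inherit its permuted label, and any information tied to identity
(e.g. dyad membership) is destroyed along with it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.random import Generator, default_rng

from .discriminant import _cv_core
from .features import FEATURE_COLUMNS

__all__ = ["PDFAResult", "permute_individuals", "pdfa"]


@dataclass
class PDFAResult:
    observed_percent_correct: float
    null_distribution: np.ndarray
    p_value: float
    n_permutations: int
    group_sizes: dict
    seed: int | None

    def report(self) -> dict:
        return {
            "observed_percent_correct": self.observed_percent_correct,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "group_sizes": {str(k): int(v) for k, v in self.group_sizes.items()},
            "null_mean": float(np.mean(self.null_distribution)),
            "null_sd": float(np.std(self.null_distribution, ddof=1)),
        }


def permute_individuals(
    animal_ids: np.ndarray | list,
    group_labels: np.ndarray | list,
    rng: Generator,
) -> np.ndarray:
    """Permute group identity at the individual level.

    ``animal_ids`` and ``group_labels`` are aligned per *individual* (one
    entry per animal -- passing per-note labels is an error); the returned
    array is the permuted label per individual, preserving the multiset of
    labels exactly.
    """
    ids = np.asarray(animal_ids)
    labels = np.asarray(group_labels)
    if len(ids) != len(np.unique(ids)):
        raise ValueError(
            "labels must be supplied per individual (one row per animal), "
            "not per note"
        )
    if len(labels) != len(ids):
        raise ValueError("animal_ids and group_labels must align")
    return labels[rng.permutation(len(labels))]


def pdfa(
    features: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    animal_col: str = "animal_id",
    n_perm: int = 1000,
    seed: int | Generator = 0,
    n_train: int = 19,
    n_test: int = 1,
    n_iter_observed: int = 100,
    n_iter_null: int = 10,
    feature_columns: list[str] | None = None,
) -> PDFAResult:
    """Permutation test of group discrimination controlling for identity.

    ``groups`` maps animal_id -> group label. The observed statistic is the
    balanced cross-validated percent correct of the group classification
    (``n_iter_observed`` random 19+1-per-animal selections); each of the
    ``n_perm`` permutations recomputes it (with ``n_iter_null`` selections)
    after reassigning group identity across individuals.

    p = (1 + #{null >= observed}) / (1 + n_perm) -- the add-one Monte-Carlo
    convention, which never returns exactly zero. For Type-I calibration
    studies set ``n_iter_observed = n_iter_null`` so the observed statistic
    is exchangeable with the null draws.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, Generator) else default_rng(seed)
    groups = dict(groups)
    animals = np.unique(features[animal_col].to_numpy())
    missing = [a for a in animals if a not in groups]
    if missing:
        raise ValueError(f"animals without a group label: {missing}")
    animal_labels = np.array([groups[a] for a in animals])
    classes = np.unique(animal_labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 groups")
    sizes = {c: int(np.sum(animal_labels == c)) for c in classes}

    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in features]
    X = features[cols].to_numpy(dtype=float)
    note_animals = features[animal_col].to_numpy()
    by_animal = [np.flatnonzero(note_animals == a) for a in animals]
    need = n_train + n_test
    short = [str(animals[i]) for i, idx in enumerate(by_animal) if len(idx) < need]
    if short:
        raise ValueError(f"animals with fewer than {need} notes: {short}")
    animal_of_note = np.searchsorted(animals, note_animals)
    class_index = {c: i for i, c in enumerate(classes)}

    def percent_correct(labels_per_animal: np.ndarray, n_iter: int) -> float:
        codes = np.array(
            [class_index[labels_per_animal[a]] for a in animal_of_note]
        )
        _, per_iter = _cv_core(
            X, codes, len(classes), by_animal, n_train, n_test, n_iter, rng
        )
        return float(np.mean(per_iter))

    observed = percent_correct(animal_labels, n_iter_observed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        permuted = permute_individuals(animals, animal_labels, rng)
        null[b] = percent_correct(permuted, n_iter_null)
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_perm)
    return PDFAResult(
        observed_percent_correct=observed,
        null_distribution=null,
        p_value=p,
        n_permutations=n_perm,
        group_sizes=sizes,
        seed=None if isinstance(seed, Generator) else int(seed),
    )
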