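"""Transfer-learning experiments over drug subcorpora.

Two designs are orchestrated here:

* **Single-subcorpus transfer** — train a model on the documents of one
  drug *i* and score it on another drug *j*, for all ordered pairs, giving
  an n-by-n matrix of macro-F1 (and accuracy) values whose diagonal is the
  in-domain case.
* **Incremental learning (Sim vs Rnd)** — for a target drug *j*, train on
  the union of the first *X* source drugs taken either in descending
  structural (Tanimoto) similarity to *j* (SIM) or in random order (RND),
  and score plain accuracy on all of *j*'s documents.  Comparing the two
  orderings as *X* grows measures whether structural similarity is a useful
  source-selection signal.

The target drug's documents never enter training or development sets; this
is asserted at document-id level on every run.  All randomness is derived
from a master seed with a splitmix-style mixer, so every cell and every
replicate is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classify import FeatureCache, TrainConfig, fit
from .corpus import Corpus, SplitSpec, oversample_balance, split, subcorpus
from .chem import SimilarityMatrix

Trainer = Callable[[Corpus, Corpus, TrainConfig, FeatureCache | None], object]

_MASK64 = 0xFFFFFFFFFFFFFFFF


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def _fnv64(s: str) -> int:
    h = 0xCBF29CE484222325
    for byte in s.encode("utf-8"):
        h = ((h ^ byte) * 0x100000001B3) & _MASK64
    return h


def derive_seed(master: int, *parts: int | str) -> int:
    """Derive an independent 31-bit seed from a master seed and context parts."""
    state = _splitmix64(master & _MASK64)
    for p in parts:
        token = _fnv64(p) if isinstance(p, str) else (int(p) & _MASK64)
        state = _splitmix64(state ^ token)
    return int(state & 0x7FFFFFFF)


@dataclass(frozen=True)
class TransferResult:
    """Scores of one trained model on one test subcorpus."""

    macro_f1: float
    accuracy: float
    n_train: int
    n_test: int


@dataclass(frozen=True)
class TransferMatrix:
    """Train-drug by test-drug score matrices from single-subcorpus transfer."""

    drug_order: tuple[str, ...]
    f1: np.ndarray = field(repr=False)
    accuracy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.drug_order)
        for name in ("f1", "accuracy"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {m.shape}")
            if m.min() < 0.0 or m.max() > 1.0:
                raise ValueError(f"{name} entries must lie in [0, 1]")
            object.__setattr__(self, name, m)

    def diagonal_mean(self) -> float:
        return float(np.mean(np.diag(self.f1)))

    def offdiagonal_mean(self) -> float:
        mask = ~np.eye(len(self.drug_order), dtype=bool)
        return float(np.mean(self.f1[mask]))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.f1, index=self.drug_order, columns=self.drug_order).to_csv(
            path, sep="\t", index_label="train\\test"
        )


def _assert_no_leakage(train: Corpus, dev: Corpus, test: Corpus) -> None:
    held_out = test.source_ids()
    leaked = (train.source_ids() | dev.source_ids()) & held_out
    if leaked:
        raise AssertionError(f"test documents leaked into training: {sorted(leaked)[:5]}")


def _train_and_score(
    source: Corpus,
    test: Corpus,
    config: TrainConfig,
    seed: int,
    ratios: tuple[float, ...],
    oversample: bool,
    cache: FeatureCache | None,
    trainer: Trainer,
) -> TransferResult:
    from . import stats

    parts = split(source, SplitSpec(ratios=ratios, seed=derive_seed(seed, "split")))
    train, dev = parts[0], parts[1]
    test_part = parts[2] if len(parts) > 2 else test
    if oversample:
        train = oversample_balance(train, seed=derive_seed(seed, "oversample"))
    _assert_no_leakage(train, dev, test_part)
    model = trainer(train, dev, replace(config, seed=derive_seed(seed, "fit")), cache)
    pred = model.predict(test_part, cache=cache) if cache is not None else model.predict(test_part)
    true = test_part.labels()
    return TransferResult(
        macro_f1=stats.macro_f1(true, pred),
        accuracy=stats.accuracy(true, pred),
        n_train=len(train),
        n_test=len(test_part),
    )


def run_single_transfer(
    corpus: Corpus,
    panel: Sequence[str],
    i: str,
    j: str,
    config: TrainConfig,
    seed: int,
    oversample: bool = True,
    cache: FeatureCache | None = None,
    trainer: Trainer = fit,
) -> TransferResult:
    """Train on drug ``i``, evaluate on drug ``j``.

    For ``i != j`` the source subcorpus is split 90:10 into train/dev and the
    whole of ``j``'s subcorpus is the test set.  For ``i == j`` the subcorpus
    is split 80:10:10 and the held-out tenth is the test set.  The training
    part is randomly oversampled to equal label proportions.
    """
    if i not in panel or j not in panel:
        raise ValueError(f"drugs {i!r}, {j!r} must be in the panel")
    d_i = subcorpus(corpus, i)
    d_j = subcorpus(corpus, j)
    if len(d_i) == 0 or len(d_j) == 0:
        raise ValueError(f"empty subcorpus for {i!r} or {j!r}")
    if i == j:
        return _train_and_score(
            d_i, d_i, config, seed, (0.8, 0.1, 0.1), oversample, cache, trainer
        )
    return _train_and_score(
        d_i, d_j, config, seed, (0.9, 0.1), oversample, cache, trainer
    )


def run_transfer_matrix(
    corpus: Corpus,
    panel: Sequence[str],
    config: TrainConfig,
    seed: int,
    oversample: bool = True,
    cache: FeatureCache | None = None,
    trainer: Trainer = fit,
) -> TransferMatrix:
    """All ordered (train drug, test drug) cells, each with its own derived seed."""
    panel = list(panel)
    if len(panel) < 2:
        raise ValueError("need at least 2 drugs")
    if cache is None and trainer is fit:
        cache = FeatureCache(corpus, config)
    n = len(panel)
    f1 = np.zeros((n, n))
    acc = np.zeros((n, n))
    for a, drug_i in enumerate(panel):
        for b, drug_j in enumerate(panel):
            res = run_single_transfer(
                corpus,
                panel,
                drug_i,
                drug_j,
                config,
                seed=derive_seed(seed, "cell", drug_i, drug_j),
                oversample=oversample,
                cache=cache,
                trainer=trainer,
            )
            f1[a, b] = res.macro_f1
            acc[a, b] = res.accuracy
    return TransferMatrix(drug_order=tuple(panel), f1=f1, accuracy=acc)


def order_by_similarity(simmat: SimilarityMatrix, target: str) -> list[str]:
    """All drugs except ``target``, by descending Tanimoto to it.

    Ties are broken by ascending drug name, making the SIM ordering a pure
    function of the similarity matrix.
    """
    t = simmat.index(target)
    others = [d for d in simmat.drug_order if d != target]
    return sorted(others, key=lambda d: (-simmat.values[simmat.index(d), t], d))


def random_ordering(drugs: Sequence[str], target: str, seed: int) -> list[str]:
    """A uniform random ordering of all drugs except ``target``."""
    others = [d for d in drugs if d != target]
    rng = np.random.default_rng(seed)
    return [others[k] for k in rng.permutation(len(others))]


def run_incremental(
    corpus: Corpus,
    panel: Sequence[str],
    target: str,
    ordering: Sequence[str],
    x: int,
    config: TrainConfig,
    seed: int,
    oversample: bool = True,
    cache: FeatureCache | None = None,
    trainer: Trainer = fit,
) -> TransferResult:
    """Train on the first ``x`` drugs of ``ordering``; test on all of ``target``.

    The pooled source corpus D_K is split 90:10 into train/dev; the target's
    subcorpus is the test set and never contributes to either.
    """
    panel = list(panel)
    if target not in panel:
        raise ValueError(f"unknown target {target!r}")
    if not 1 <= x <= len(panel) - 1:
        raise ValueError(f"x must be in [1, {len(panel) - 1}], got {x}")
    if target in ordering:
        raise ValueError("ordering must exclude the target drug")
    sources = list(ordering[:x])
    d_k = subcorpus(corpus, sources)
    d_j = subcorpus(corpus, target)
    if len(d_k) == 0 or len(d_j) == 0:
        raise ValueError("empty source or target subcorpus")
    return _train_and_score(
        d_k, d_j, config, seed, (0.9, 0.1), oversample, cache, trainer
    )


def sim_vs_rnd(
    corpus: Corpus,
    panel: Sequence[str],
    simmat: SimilarityMatrix,
    x_list: Sequence[int],
    config: TrainConfig,
    seed: int,
    n_rnd_reps: int = 10,
    oversample: bool = True,
    cache: FeatureCache | None = None,
    trainer: Trainer = fit,
) -> pd.DataFrame:
    """Per-target, per-X accuracies under SIM and RND source orderings.

    Returns a tidy frame with one row per (target, X, policy, replicate):
    SIM has a single deterministic run per (target, X); RND has
    ``n_rnd_reps`` independent orderings.  The whole table is a pure
    function of the master seed.
    """
    panel = list(panel)
    if sorted(panel) != sorted(simmat.drug_order):
        raise ValueError("panel and similarity matrix must contain the same drugs")
    for x in x_list:
        if not 1 <= x <= len(panel) - 1:
            raise ValueError(f"X={x} outside [1, {len(panel) - 1}]")
    if cache is None and trainer is fit:
        cache = FeatureCache(corpus, config)
    rows = []
    for target in panel:
        sim_order = order_by_similarity(simmat, target)
        rnd_orders = [
            random_ordering(panel, target, derive_seed(seed, "rnd-order", target, rep))
            for rep in range(n_rnd_reps)
        ]
        for x in x_list:
            res = run_incremental(
                corpus, panel, target, sim_order, x, config,
                seed=derive_seed(seed, "sim", target, x),
                oversample=oversample, cache=cache, trainer=trainer,
            )
            rows.append(
                {"target": target, "x": x, "policy": "sim", "rep": 0,
                 "accuracy": res.accuracy, "macro_f1": res.macro_f1}
            )
            for rep, order in enumerate(rnd_orders):
                res = run_incremental(
                    corpus, panel, target, order, x, config,
                    seed=derive_seed(seed, "rnd", target, x, rep),
                    oversample=oversample, cache=cache, trainer=trainer,
                )
                rows.append(
                    {"target": target, "x": x, "policy": "rnd", "rep": rep,
                     "accuracy": res.accuracy, "macro_f1": res.macro_f1}
                )
    return pd.DataFrame(rows)


def sim_vs_rnd_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per (X, policy) across targets, with standard errors.

    RND replicates are first averaged within each target, matching how a
    replicated random baseline is reported against the single SIM run; the
    ``sem`` column is the standard error of the per-target means.
    """
    per_target = (
        table.groupby(["x", "policy", "target"], as_index=False)["accuracy"].mean()
    )
    out = per_target.groupby(["x", "policy"])["accuracy"].agg(
        mean_accuracy="mean",
        sem=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        n_targets="count",
    )
    return out.reset_index()
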