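"""Synthetic proteomes and balanced labeled pair sets with a planted signal.

The generator emulates the structure of balanced PPI benchmark sets: a
proteome of natural-alphabet sequences and an equal number of interacting
and non-interacting pairs.  A known subset of dipeptide compositions
carries the interaction signal, so selection-recovery and evaluation
behavior can be tested against ground truth without any downloads.

Construction
------------
* Half of the proteins (chosen at random) are *signal* proteins.  Their
  sequences are drawn from a first-order Markov chain whose transition
  matrix boosts the planted dipeptides while keeping the stationary
  letter distribution equal to the background (biproportional fitting), and
  are rejection-sampled until every planted dipeptide's composition exceeds
  ``enrichment_factor`` times its background expectation.  Background
  proteins are i.i.d. draws from the background letter frequencies.
* For a pool of candidate pairs, the interaction probability is
  ``sigmoid(alpha - beta * z)`` where ``z`` is the standardized sum of
  planted ``|delta DPC|`` values and ``alpha`` is calibrated so the
  marginal positive rate is 0.5.  Sampled labels are then down-sampled to
  exact class balance.

Because pairs of *similar* proteins interact, the planted coefficient is
negative on the difference features, matching the view that large
physicochemical differences disfavor interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np

from .seq_io import STANDARD_AA, LabeledPair, ProteinRecord

logger = logging.getLogger(__name__)

_AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}


class GenerationError(RuntimeError):
    """The generator could not satisfy its configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 300 proteins of 100-300 residues over a uniform background,
    four planted dipeptides (VV, KK, IK, EE) enriched threefold in the
    signal subpopulation, 500 pairs per class, and a standardized logistic
    effect size of 2.5 (log-odds per standard deviation of the planted
    difference sum).
    """

    n_proteins: int = 300
    length_range: tuple[int, int] = (100, 300)
    planted_dipeptides: tuple[str, ...] = ("VV", "KK", "IK", "EE")
    effect_size: float = 2.5
    n_pairs_per_class: int = 500
    background: tuple[float, ...] = tuple([0.05] * 20)
    enrichment_factor: float = 3.0
    seed: int = 0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.size != 20 or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise GenerationError(
                "background must be 20 positive frequencies summing to 1"
            )
        for dp in self.planted_dipeptides:
            if len(dp) != 2 or any(a not in _AA_INDEX for a in dp):
                raise GenerationError(f"invalid planted dipeptide {dp!r}")
        if self.n_pairs_per_class < 1:
            raise GenerationError("n_pairs_per_class must be >= 1")
        if self.effect_size < 0:
            raise GenerationError("effect_size must be >= 0")
        if self.enrichment_factor <= 1:
            raise GenerationError("enrichment_factor must be > 1")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise GenerationError("invalid length_range")


@dataclass(frozen=True)
class SyntheticProteome:
    """Generated records plus the hidden signal-subpopulation tags."""

    records: tuple[ProteinRecord, ...]
    signal_ids: frozenset[str]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class Truth:
    """Ground truth of a generated pair set."""

    planted_dipeptides: tuple[str, ...]
    planted_features: tuple[str, ...]
    linear_predictor: np.ndarray  # alpha - beta * z, aligned with pairs
    probability: np.ndarray
    alpha: float
    beta: float


@dataclass(frozen=True)
class SyntheticDataset:
    proteins: SyntheticProteome
    pairs: tuple[LabeledPair, ...]
    truth: Truth


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

def _signal_transition_matrix(config: SyntheticConfig) -> np.ndarray:
    """Markov transitions hitting planted dipeptide targets.

    Planted entries are fixed so the chain's expected dipeptide frequency
    is ~1.5x the rejection threshold (headroom keeps the rejection rate
    low); the remaining entries are biproportionally rescaled so the
    stationary letter distribution stays at the background frequencies.
    """
    bg = np.asarray(config.background, dtype=float)
    # joint dipeptide frequencies Q[x, y] = pi_x * P(y|x); start independent
    q = np.outer(bg, bg)
    fixed = np.zeros((20, 20), dtype=bool)
    headroom = 1.5
    for dp in config.planted_dipeptides:
        x, y = _AA_INDEX[dp[0]], _AA_INDEX[dp[1]]
        target = headroom * config.enrichment_factor * bg[x] * bg[y]
        if target >= 0.9 * min(bg[x], bg[y]):
            raise GenerationError(
                f"enrichment_factor {config.enrichment_factor} infeasible "
                f"for dipeptide {dp} at the given background"
            )
        q[x, y] = target
        fixed[x, y] = True
    # biproportional fitting of the free cells to row/col sums = background
    for _ in range(200):
        row_free = bg - np.where(fixed, q, 0.0).sum(axis=1)
        row_now = np.where(fixed, 0.0, q).sum(axis=1)
        q[~fixed] = (q * (row_free / row_now)[:, None])[~fixed]
        col_free = bg - np.where(fixed, q, 0.0).sum(axis=0)
        col_now = np.where(fixed, 0.0, q).sum(axis=0)
        q[~fixed] = (q * (col_free / col_now)[None, :])[~fixed]
        if (
            np.abs(q.sum(axis=1) - bg).max() < 1e-12
            and np.abs(q.sum(axis=0) - bg).max() < 1e-12
        ):
            break
    if np.any(q < 0):
        raise GenerationError("enrichment infeasible: negative transition mass")
    return q / q.sum(axis=1, keepdims=True)  # P(y|x)


def _sample_markov(
    rng: np.random.Generator, trans_cum: np.ndarray, start_cum: np.ndarray, n: int
) -> np.ndarray:
    u = rng.random(n)
    seq = np.empty(n, dtype=np.intp)
    seq[0] = np.searchsorted(start_cum, u[0], side="right")
    for i in range(1, n):
        seq[i] = np.searchsorted(trans_cum[seq[i - 1]], u[i], side="right")
    return seq


def _planted_dpc(codes: np.ndarray, planted_idx: np.ndarray) -> np.ndarray:
    """DPC values of the planted dipeptides for one coded sequence."""
    pair_codes = codes[:-1] * 20 + codes[1:]
    counts = np.bincount(pair_codes, minlength=400)
    return counts[planted_idx] / (codes.size - 1)


def generate_proteome(config: SyntheticConfig) -> SyntheticProteome:
    """Generate the proteome; deterministic given ``config.seed``.

    Signal proteins are resampled (up to ``max_attempts`` rounds) until
    each planted dipeptide's composition reaches ``enrichment_factor``
    times its background expectation.
    """
    rng = np.random.default_rng(config.seed)
    bg = np.asarray(config.background, dtype=float)
    n_signal = config.n_proteins // 2
    signal_mask = np.zeros(config.n_proteins, dtype=bool)
    signal_mask[rng.permutation(config.n_proteins)[:n_signal]] = True

    planted_idx = np.array(
        [_AA_INDEX[dp[0]] * 20 + _AA_INDEX[dp[1]] for dp in config.planted_dipeptides]
    )
    thresholds = np.array(
        [
            config.enrichment_factor * bg[_AA_INDEX[dp[0]]] * bg[_AA_INDEX[dp[1]]]
            for dp in config.planted_dipeptides
        ]
    )
    trans = _signal_transition_matrix(config)
    trans_cum = np.cumsum(trans, axis=1)
    start_cum = np.cumsum(bg)
    letters = np.array(list(STANDARD_AA))

    lo, hi = config.length_range
    records: list[ProteinRecord] = []
    signal_ids: set[str] = set()
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        pid = f"P{i:0{width}d}"
        if signal_mask[i]:
            for attempt in range(config.max_attempts):
                codes = _sample_markov(rng, trans_cum, start_cum, n)
                if np.all(_planted_dpc(codes, planted_idx) >= thresholds):
                    break
            else:
                raise GenerationError(
                    f"could not enrich planted dipeptides in {pid} after "
                    f"{config.max_attempts} attempts; lower enrichment_factor "
                    f"or lengthen sequences"
                )
            signal_ids.add(pid)
        else:
            codes = rng.choice(20, size=n, p=bg)
        records.append(ProteinRecord(pid, "".join(letters[codes])))
    return SyntheticProteome(tuple(records), frozenset(signal_ids))


# ---------------------------------------------------------------------------
# Pair generation
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _calibrate_alpha(beta_z: np.ndarray) -> float:
    """Solve mean(sigmoid(alpha - beta_z)) = 0.5 for alpha by bisection."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.mean(_sigmoid(mid - beta_z)) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_pairs(
    proteome: SyntheticProteome, config: SyntheticConfig
) -> SyntheticDataset:
    """Sample a balanced labeled pair set over the proteome.

    Interaction probability for a candidate pair is
    ``sigmoid(alpha - beta * z)`` with ``z`` the standardized sum of planted
    ``|delta DPC|``; classes are down-sampled to exactly
    ``n_pairs_per_class`` each.
    """
    rng = np.random.default_rng(config.seed + 1)
    records = proteome.records
    n = len(records)
    if n < 3:
        raise GenerationError("need at least 3 proteins to draw pairs")

    planted_idx = np.array(
        [_AA_INDEX[dp[0]] * 20 + _AA_INDEX[dp[1]] for dp in config.planted_dipeptides]
    )
    dpc = np.stack(
        [
            _planted_dpc(
                np.array([_AA_INDEX[a] for a in rec.sequence], dtype=np.intp),
                planted_idx,
            )
            for rec in records
        ]
    )

    n_candidates = max(8 * config.n_pairs_per_class, 2000)
    n_possible = n * (n - 1) // 2
    n_candidates = min(n_candidates, n_possible)
    flat = rng.choice(n_possible, size=n_candidates, replace=False)
    # decode unordered pair index -> (i, j), i < j
    i_idx = (
        n - 2 - np.floor(
            np.sqrt(-8.0 * flat + 4.0 * n * (n - 1) - 7.0) / 2.0 - 0.5
        )
    ).astype(np.intp)
    j_idx = (
        flat + i_idx + 1 - n * (n - 1) // 2 + (n - i_idx) * ((n - i_idx) - 1) // 2
    ).astype(np.intp)

    s = np.abs(dpc[i_idx] - dpc[j_idx]).sum(axis=1)
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    beta_z = config.effect_size * z
    alpha = _calibrate_alpha(beta_z)
    prob = _sigmoid(alpha - beta_z)
    labels = (rng.random(n_candidates) < prob).astype(int)

    keep: list[int] = []
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        if idx.size < config.n_pairs_per_class:
            raise GenerationError(
                f"only {idx.size} class-{cls} candidates for "
                f"{config.n_pairs_per_class} requested; increase n_proteins"
            )
        keep.extend(idx[: config.n_pairs_per_class])
    keep_arr = np.array(sorted(keep))

    pairs = tuple(
        LabeledPair(records[i_idx[k]].id, records[j_idx[k]].id, int(labels[k]))
        for k in keep_arr
    )
    truth = Truth(
        planted_dipeptides=tuple(config.planted_dipeptides),
        planted_features=tuple(f"DPC_{dp}" for dp in config.planted_dipeptides),
        linear_predictor=(alpha - beta_z)[keep_arr],
        probability=prob[keep_arr],
        alpha=float(alpha),
        beta=float(config.effect_size),
    )
    return SyntheticDataset(proteome, pairs, truth)


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Proteome plus balanced pair set in one call."""
    config = config or SyntheticConfig()
    return generate_pairs(generate_proteome(config), config)


def bayes_accuracy(truth: Truth) -> float:
    """Expected accuracy of the oracle thresholding the linear predictor at 0.

    The oracle predicts 1 when the true interaction probability exceeds
    0.5 and is correct with probability ``max(p, 1 - p)``; no classifier on
    these features can beat it in expectation.
    """
    p = truth.probability
    return float(np.maximum(p, 1.0 - p).mean())
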