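"""Consensus ranking by Spearman-footrule distance.

Combines the ordered lists produced by the four stability algorithms into a
single consensus order, either exhaustively (small universes — the exact
oracle) or with the cross-entropy Monte Carlo scheme: candidate orders are
sampled from a positional probability matrix, the elite fraction with the
lowest summed footrule distance pulls the matrix toward itself, and the
procedure iterates to convergence.

Lists may carry per-item scores; the weighted footrule then measures each
item's displacement on the reference list's normalized score ladder rather
than in raw positions, so near-tied items cost little to swap.  Ties inside
a list are expressed as shared fractional ranks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np


def _rank_map(order, universe, k: int) -> dict:
    """Item -> 1-based rank; items absent from a partial list get k + 1."""
    ranks = {item: float(k + 1) for item in universe}
    for pos, item in enumerate(order, start=1):
        ranks[item] = float(pos)
    return ranks


def _weight_ladder(scores, k: int) -> np.ndarray:
    """Normalized score at positions 1..k+1 (index 0 unused).

    Scores accompany a best-first list; the ladder maps a rank to the
    normalized score a list assigns to that position, with the beyond-list
    position k+1 carrying the worst weight.
    """
    s = np.asarray(scores, dtype=float)
    spread = s.max() - s.min()
    if spread == 0:
        return None  # degenerate: fall back to unweighted
    w = (s - s.min()) / spread
    ladder = np.empty(k + 2)
    ladder[1 : k + 1] = w
    ladder[k + 1] = w[-1]
    ladder[0] = w[0]
    return ladder


def footrule_distance(candidate, reference, weights=None) -> float:
    """Spearman footrule between a candidate order and one reference list.

    Unweighted: sum_i |rank_cand(i) - rank_ref(i)|.  With ``weights`` (the
    reference list's best-first scores), each item's displacement is the
    absolute difference of the normalized reference score at its two
    positions.  ``reference`` may also be a dict item -> fractional rank to
    express ties.
    """
    if isinstance(reference, dict):
        universe = set(reference)
        ref_ranks = {i: float(r) for i, r in reference.items()}
    else:
        universe = set(reference)
        ref_ranks = _rank_map(list(reference), universe, len(reference))
    if set(candidate) - universe:
        raise ValueError("candidate contains items outside the reference universe")
    k = max(len(candidate), len(universe))
    cand_ranks = _rank_map(list(candidate), universe, k)
    if weights is not None:
        ladder = _weight_ladder(weights, k)
        if ladder is not None:
            xs = np.arange(len(ladder))
            total = 0.0
            for item in universe:
                wc = np.interp(cand_ranks[item], xs, ladder)
                wr = np.interp(ref_ranks[item], xs, ladder)
                total += abs(wc - wr)
            return float(total)
    return float(sum(abs(cand_ranks[i] - ref_ranks[i]) for i in universe))


def _objective(candidate, lists, weights) -> float:
    ws = weights if weights is not None else [None] * len(lists)
    return sum(footrule_distance(candidate, l, w) for l, w in zip(lists, ws))


@dataclass
class AggregateRanking:
    order: tuple
    objective: float
    method: str
    iterations: int = 0
    converged: bool = True
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "order": list(self.order),
            "objective": self.objective,
            "method": self.method,
            "iterations": self.iterations,
            "converged": self.converged,
            "seed": self.seed,
        }


def _universe(lists) -> list:
    universe = set()
    for l in lists:
        items = set(l if not isinstance(l, dict) else l.keys())
        universe |= items
    for l in lists:
        items = set(l if not isinstance(l, dict) else l.keys())
        if items != universe:
            raise ValueError("all input lists must share the same item universe")
    return sorted(universe)


def aggregate_bruteforce(lists, k: int | None = None, weights=None) -> AggregateRanking:
    """Exact consensus by exhaustive enumeration of all k-permutations.

    Refuses universes above 8 items; ties between optimal orders break
    lexicographically (enumeration order).
    """
    universe = _universe(lists)
    n = len(universe)
    if n > 8:
        raise ValueError(f"exhaustive aggregation limited to 8 items, got {n}")
    k = n if k is None else k
    best_order, best_obj = None, np.inf
    for cand in itertools.permutations(universe, k):
        obj = _objective(cand, lists, weights)
        if obj < best_obj:
            best_order, best_obj = cand, obj
    return AggregateRanking(best_order, float(best_obj), "bruteforce")


def aggregate_ce_mc(
    lists,
    k: int | None = None,
    n_samples: int | None = None,
    rho: float = 0.1,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    weights=None,
    learning_rate: float = 0.3,
) -> AggregateRanking:
    """Cross-entropy Monte Carlo consensus under the footrule objective.

    Orders are sampled position by position from a (position x item)
    probability matrix; the rho-quantile elite updates the matrix toward its
    empirical positional frequencies with the given learning rate, until the
    matrix moves less than ``tol`` or ``max_iter`` is hit.  Deterministic
    for a fixed seed; the best order ever sampled is returned.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"rho must lie in (0, 1), got {rho}")
    if len(lists) < 2:
        raise ValueError("need at least 2 input lists")
    universe = _universe(lists)
    n = len(universe)
    k = n if k is None else k
    if k != n:
        raise ValueError("cross-entropy aggregation orders the full universe (k = n)")
    if n_samples is None:
        n_samples = max(10 * k * k, 50)
    rng = np.random.default_rng(seed)
    item_idx = {it: i for i, it in enumerate(universe)}

    # precompute reference rank vectors / weight ladders on integer item ids
    ref_ranks = []
    ladders = []
    ws = weights if weights is not None else [None] * len(lists)
    for l, w in zip(lists, ws):
        if isinstance(l, dict):
            rmap = {item_idx[i]: float(r) for i, r in l.items()}
        else:
            rmap = {item_idx[i]: float(p) for p, i in enumerate(l, start=1)}
        ref_ranks.append(np.array([rmap[i] for i in range(n)]))
        ladders.append(_weight_ladder(w, k) if w is not None else None)

    def objectives(samples: np.ndarray) -> np.ndarray:
        s = samples.shape[0]
        pos = np.empty((s, n))
        pos[np.arange(s)[:, None], samples] = np.arange(1, k + 1)[None, :]
        total = np.zeros(s)
        for r, ladder in zip(ref_ranks, ladders):
            if ladder is None:
                total += np.abs(pos - r[None, :]).sum(axis=1)
            else:
                xs = np.arange(len(ladder))
                total += np.abs(
                    np.interp(pos, xs, ladder) - np.interp(r, xs, ladder)[None, :]
                ).sum(axis=1)
        return total

    def sample_orders(prob: np.ndarray, count: int) -> np.ndarray:
        orders = np.empty((count, k), dtype=int)
        avail = np.ones((count, n))
        u = rng.random((count, k))
        for pos in range(k):
            p = prob[pos][None, :] * avail
            cdf = np.cumsum(p, axis=1)
            cdf /= cdf[:, -1:]
            choice = (u[:, pos : pos + 1] > cdf).sum(axis=1)
            orders[:, pos] = choice
            avail[np.arange(count), choice] = 0.0
        return orders

    prob = np.full((k, n), 1.0 / n)
    best_order, best_obj = None, np.inf
    n_elite = max(1, int(np.ceil(rho * n_samples)))
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        samples = sample_orders(prob, n_samples)
        objs = objectives(samples)
        elite = samples[np.argsort(objs, kind="stable")[:n_elite]]
        i_best = int(np.argmin(objs))
        if objs[i_best] < best_obj:
            best_obj = float(objs[i_best])
            best_order = samples[i_best].copy()
        freq = np.zeros((k, n))
        np.add.at(freq, (np.arange(k)[None, :], elite), 1.0)
        freq /= len(elite)
        new_prob = (1.0 - learning_rate) * prob + learning_rate * freq
        new_prob /= new_prob.sum(axis=1, keepdims=True)
        delta = float(np.abs(new_prob - prob).max())
        prob = new_prob
        if delta < tol:
            converged = True
            break
    order_items = tuple(universe[i] for i in best_order)
    return AggregateRanking(
        order_items, float(best_obj), "ce_mc", iterations, converged, seed
    )
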