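"""Evaluation protocols: input-order stability and complexity reporting.

The construction is deterministic but not symmetric in its input: tie-breaks
follow the first-encounter order of taxa, which the cluster-line order of
the input file induces.  The *permutation stability* protocol quantifies
this by rebuilding the network for every permutation of the cluster lines,
counting the distinct results (by canonical form) and summarizing their
pairwise tripartition distances.  The *complexity report* tabulates, per
input, the cluster and taxon counts together with the constructed network's
level ``k``, reticulation number ``r``, redundant-cluster count ``c`` and
the wall-clock build time ``t``.
"""

from __future__ import annotations

import itertools
import math
import random
import time
from dataclasses import dataclass

from .builder import BuildConfig, build
from .clusters import ClusterSet
from .errors import ResourceError
from .network import PhyloNetwork
from .tripartition import tripartition_distance

__all__ = [
    "StabilityReport",
    "complexity_report",
    "permutation_stability",
]


@dataclass(frozen=True)
class StabilityReport:
    """Distinct-network count and tripartition-distance statistics over the
    permutations of a cluster set's input order."""

    n: int
    min: float
    max: float
    mean: float
    permutations_run: int
    networks: tuple[PhyloNetwork, ...] = ()

    def __post_init__(self):
        assert self.n >= 1
        assert self.min <= self.mean <= self.max or self.n == 1


def _taxa_order(orders, universe_order) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for o in orders:
        for t in o:
            seen.setdefault(t, None)
    for t in universe_order:
        seen.setdefault(t, None)
    return tuple(seen)


def permutation_stability(y: ClusterSet, cfg: BuildConfig | None = None,
                          limit: int = 5040,
                          seed: int | None = None) -> StabilityReport:
    """Rebuild the network for every cluster-order permutation of ``y``.

    All ``|Y|!`` permutations are run when they fit under ``limit``;
    otherwise ``limit`` permutations are subsampled uniformly with ``seed``
    (a missing seed raises).  Distinct networks are counted by canonical
    form; the pairwise tripartition-distance mean is rounded to two decimals
    (all statistics are 0 when a single network results).

    The build outcome depends on the input order only through the induced
    taxon first-encounter order, so permutations sharing that order share
    one build.
    """
    from .network import canonical_form

    cfg = cfg or BuildConfig()
    orders = y.cluster_orders
    total = math.factorial(len(orders))
    if total <= limit:
        perms = itertools.permutations(orders)
        n_run = total
    else:
        if seed is None:
            raise ResourceError(
                f"{total} permutations exceed limit {limit}; pass a seed to subsample")
        rng = random.Random(seed)
        perms = []
        for _ in range(limit):
            p = list(orders)
            rng.shuffle(p)
            perms.append(tuple(p))
        n_run = limit
    cache: dict[tuple, str] = {}
    distinct: dict[str, PhyloNetwork] = {}
    for perm in perms:
        key = _taxa_order(perm, y.taxa)
        form = cache.get(key)
        if form is None:
            cand = build(ClusterSet(perm, universe=key), cfg)
            form = cand.form
            cache[key] = form
            distinct.setdefault(form, cand.network)
        # distinct networks already recorded on first sighting
    nets = [distinct[f] for f in sorted(distinct)]
    if len(nets) == 1:
        return StabilityReport(1, 0.0, 0.0, 0.0, n_run, tuple(nets))
    dists = [tripartition_distance(a, b)
             for a, b in itertools.combinations(nets, 2)]
    return StabilityReport(
        n=len(nets),
        min=min(dists),
        max=max(dists),
        mean=round(sum(dists) / len(dists), 2),
        permutations_run=n_run,
        networks=tuple(nets),
    )


def complexity_report(inputs: list[tuple[str, ClusterSet]],
                      cfg: BuildConfig | None = None) -> dict:
    """Per-input build statistics plus a final row of column means.

    Returns ``{"rows": [...], "means": {...}}``; each row carries the input
    name, ``C`` (cluster count), ``X`` (taxon count), ``t`` (seconds),
    ``k`` (network level), ``r`` and ``c``.  Failures are recorded in the
    row's ``error`` field and excluded from the means.
    """
    cfg = cfg or BuildConfig()
    rows = []
    for name, y in inputs:
        row = {"name": name, "C": len(y), "X": len(y.universe)}
        start = time.perf_counter()
        try:
            cand = build(y, cfg)
        except Exception as exc:  # per-input failures are recorded, not fatal
            row.update(t=round(time.perf_counter() - start, 3), error=str(exc))
        else:
            row.update(t=round(time.perf_counter() - start, 3),
                       k=cand.level, r=cand.r, c=cand.c)
        rows.append(row)
    ok = [r for r in rows if "error" not in r]
    means = {}
    if ok:
        for col in ("C", "X", "t", "k", "r", "c"):
            means[col] = round(sum(r[col] for r in ok) / len(ok), 2)
    return {"rows": rows, "means": means}
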