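"""Preranked gene-set enrichment: running-sum enrichment score, gene-label
permutation null, NES, and BH multiplicity control, with GMT I/O.

Walking down the ranked list, each gene-set member ("hit") increments the
running sum by its weighted statistic share ``|s|^w / sum_hits |s|^w`` and
each non-member decrements it by ``1 / (N - n_hits)``.  The enrichment score
(ES) is the running-sum value of maximal absolute deviation from zero.  The
null is built by drawing random same-size gene sets from the universe (the
only permutation scheme available for preranked input); NES divides ES by
the mean |null ES| of matching sign, and the nominal p is the same-sign
exceedance fraction with an add-one correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .stats import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with the bookkeeping from loading."""

    sets: dict                      # name -> list of member symbols
    descriptions: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)   # name -> reason

    def __len__(self):
        return len(self.sets)


def read_gmt(path, universe=None, min_size: int = 5, max_size: int = 500
             ) -> GeneSetCollection:
    """Parse a GMT file (name, description, tab-separated members).

    Duplicate members within a line are deduplicated (logged in
    ``dropped``); when a ``universe`` is given, sets are intersected with it
    first.  Size bounds are applied after intersection; out-of-bounds sets
    are dropped with the reason recorded.
    """
    sets, desc, dropped = {}, {}, {}
    universe_set = set(universe) if universe is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: expected at least "
                    "3 tab-separated fields")
            name, description = fields[0], fields[1]
            if name in sets or name in dropped:
                raise ValueError(
                    f"{path}: duplicate set name {name!r} at line {lineno}")
            members, seen = [], set()
            dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                members.append(g)
            if dups:
                dropped.setdefault(f"{name}::duplicates",
                                   f"{dups} duplicate members deduplicated")
            if universe_set is not None:
                members = [g for g in members if g in universe_set]
            if len(members) < min_size:
                dropped[name] = f"size {len(members)} < min {min_size}"
                continue
            if len(members) > max_size:
                dropped[name] = f"size {len(members)} > max {max_size}"
                continue
            sets[name] = members
            desc[name] = description
    return GeneSetCollection(sets, desc, dropped)


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, descriptions.get(name, "na"),
                                *members]) + "\n")


def make_ranked_list(stats) -> pd.Series:
    """Order a gene -> statistic mapping descending, ties broken by symbol.

    Duplicate symbols or non-finite statistics are errors.
    """
    s = pd.Series(stats, dtype=float)
    if s.index.duplicated().any():
        dup = list(s.index[s.index.duplicated()].unique())
        raise ValueError(f"duplicate gene symbols in ranking: {dup}")
    if not np.isfinite(s.values).all():
        raise ValueError("ranking statistics must be finite")
    order = np.lexsort((np.asarray(s.index, dtype=object), -s.values))
    return s.iloc[order]


def _es_curve(stat: np.ndarray, hits: np.ndarray, weight_exponent: float):
    """Running sum for one ranked list / hit indicator pair."""
    N = len(stat)
    nh = int(hits.sum())
    if nh == 0:
        raise ValueError("gene set has empty intersection with the universe")
    if nh == N:
        miss_step = 0.0
    else:
        miss_step = 1.0 / (N - nh)
    w = np.abs(stat) ** weight_exponent
    hw = np.where(hits, w, 0.0)
    denom = hw.sum()
    if denom == 0:      # all-zero statistics: fall back to equal hit weights
        hw = hits.astype(float)
        denom = hw.sum()
    steps = hw / denom - np.where(hits, 0.0, miss_step)
    return np.cumsum(steps)


@dataclass
class EnrichmentResult:
    es: float
    running: np.ndarray
    peak: int                 # index of the extremum in the ranked list
    leading_edge: list


def enrichment_score(ranked: pd.Series, geneset,
                     weight_exponent: float = 1.0) -> EnrichmentResult:
    """Weighted running-sum enrichment score of one gene set.

    The leading edge holds the set members at or before the extremum for
    positive ES, and at or after it for negative ES.
    """
    genes = np.asarray(ranked.index, dtype=object)
    stat = ranked.values.astype(float)
    members = set(geneset)
    hits = np.fromiter((g in members for g in genes), bool, len(genes))
    running = _es_curve(stat, hits, weight_exponent)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        le = [g for g, h in zip(genes[:peak + 1], hits[:peak + 1]) if h]
    else:
        le = [g for g, h in zip(genes[peak:], hits[peak:]) if h]
    return EnrichmentResult(es, running, peak, le)


def _null_es(stat: np.ndarray, size: int, n_perm: int,
             rng: np.random.Generator, weight_exponent: float) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets (vectorized)."""
    N = len(stat)
    if size > N:
        raise ValueError("gene set larger than the ranked universe")
    keys = rng.random((n_perm, N))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    hits = np.zeros((n_perm, N), bool)
    np.put_along_axis(hits, idx, True, axis=1)
    w = np.abs(stat) ** weight_exponent
    hw = hits * w
    denom = hw.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        hw[zero] = hits[zero].astype(float)
        denom = hw.sum(axis=1, keepdims=True)
    miss_step = 1.0 / (N - size) if size < N else 0.0
    steps = hw / denom - (~hits) * miss_step
    running = np.cumsum(steps, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), peaks]


def preranked_gsea(ranked: pd.Series, collection: GeneSetCollection,
                   n_perm: int = 1000, seed=0,
                   weight_exponent: float = 1.0) -> pd.DataFrame:
    """Permutation GSEA over a collection; one row per set.

    NES = ES / mean(|null ES| of matching sign); nominal
    p = (1 + #{same-sign |null ES| >= |ES|}) / (1 + #same-sign); BH across
    sets.  Determinism: the same seed yields identical NES and p.
    """
    if len(collection.sets) == 0:
        raise ValueError("empty gene-set collection")
    ranked = make_ranked_list(ranked)
    stat = ranked.values.astype(float)
    universe = set(ranked.index)
    rng = np.random.default_rng(seed)
    eff_sets = {}
    for name in collection.sets:
        if len(collection.sets[name]) > len(ranked):
            raise ValueError(
                f"set {name!r} is larger than the ranked universe")
        eff = [g for g in collection.sets[name] if g in universe]
        if not eff:
            raise ValueError(
                f"set {name!r} has empty intersection with the universe")
        eff_sets[name] = eff
    null_cache = {}
    sizes = sorted({len(v) for v in eff_sets.values()})
    for size in sizes:
        null_cache[size] = _null_es(stat, size, n_perm, rng, weight_exponent)
    rows = []
    for name, members in eff_sets.items():
        res = enrichment_score(ranked, members, weight_exponent)
        null = null_cache[len(members)]
        same = null > 0 if res.es >= 0 else null < 0
        n_same = int(same.sum())
        if n_same == 0:
            warnings.warn(f"no same-sign null ES for set {name!r}")
            denom = np.abs(null).mean() or 1.0
            nes = res.es / denom
            p = 1.0
        else:
            nes = res.es / np.abs(null[same]).mean()
            p = (1.0 + np.sum(np.abs(null[same]) >= abs(res.es))) / (1.0 + n_same)
        rows.append({"set": name, "size": len(members), "es": res.es,
                     "nes": nes, "p": p,
                     "leading_edge": ";".join(res.leading_edge)})
    out = pd.DataFrame(rows).set_index("set")
    out["p_adj"] = bh_adjust(out["p"].values)
    return out[["size", "es", "nes", "p", "p_adj", "leading_edge"]]


def two_class_report(results: pd.DataFrame, alpha: float = 0.05):
    """Split significant sets (adjusted p < alpha) by NES sign.

    Returns ``(up, down)`` tables sorted by |NES| descending; the partition
    over significant sets is exhaustive and disjoint.
    """
    sig = results[results["p_adj"] < alpha]
    up = sig[sig["nes"] > 0]
    down = sig[sig["nes"] < 0]
    key = lambda df: df.reindex(df["nes"].abs().sort_values(ascending=False).index)  # noqa: E731
    return key(up), key(down)
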