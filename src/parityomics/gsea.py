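"""Gene-set enrichment analysis with a gene-set permutation null.

A ranked gene list (here: parous-minus-virgin mean expression
difference) is walked from top to bottom while a running sum is
incremented at set members (by |score|^p, normalised over the set) and
decremented at non-members (by 1/(N-k)).  The enrichment score ES is the
signed maximum deviation of this walk.  Significance comes from random
same-size gene sets: the nominal p is the same-sign null tail, NES
divides ES by the mean same-sign null |ES|, the FDR q-value is the
tail-ratio over the pooled normalised null, and the FWER compares each
observed NES against the per-permutation most extreme null NES.  The
gene-set (rather than phenotype) permutation null is the appropriate
choice at very small replicate numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "GeneSetCollection",
    "GeneSetEnrichment",
    "read_gmt",
    "write_gmt",
    "rank_by_difference",
    "enrichment_score",
    "permute_and_score",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def size_flags(self, min_size: int, max_size: int) -> dict[str, str]:
        """Flag (never drop) sets outside the [min_size, max_size] band."""
        flags = {}
        for name, members in self.sets.items():
            if len(members) < min_size:
                flags[name] = "below_min_size"
            elif len(members) > max_size:
                flags[name] = "above_max_size"
            else:
                flags[name] = "ok"
        return flags


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-separated GMT file: name, description, member genes."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = frozenset(g for g in fields[2:] if g)
            descriptions[fields[0]] = fields[1]
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def rank_by_difference(
    expr_parous: pd.DataFrame, expr_virgin: pd.DataFrame
) -> pd.Series:
    """Rank genes by mean(parous) - mean(virgin), descending.

    Ties are broken lexicographically by gene id for determinism.
    """
    shared = expr_parous.index.intersection(expr_virgin.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the two matrices")
    score = expr_parous.loc[shared].mean(axis=1) - expr_virgin.loc[shared].mean(axis=1)
    frame = score.to_frame("score")
    frame["gene"] = frame.index
    frame = frame.sort_values(["score", "gene"], ascending=[False, True])
    return frame["score"]


def _validate_ranked(ranked: pd.Series) -> pd.Series:
    if ranked.index.has_duplicates:
        raise ValueError("ranked list has duplicate gene ids")
    if not np.isfinite(ranked.to_numpy(float)).all():
        raise ValueError("ranking scores must be finite")
    if np.any(np.diff(ranked.to_numpy(float)) > 0):
        raise ValueError("ranked list must be sorted in descending score order")
    return ranked


def enrichment_score(
    ranked: pd.Series, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov enrichment score and running sum.

    Returns (ES, running_sum) where the running sum has one value per
    ranked position and, by construction of the normalised increments,
    returns to 0 at the end of the list.
    """
    ranked = _validate_ranked(ranked)
    hits = ranked.index.isin(set(gene_set))
    k = int(hits.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    N = len(ranked)
    if k == N:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.to_numpy(float)) ** weight_exponent
    hit_weight = np.where(hits, w, 0.0)
    total = hit_weight.sum()
    if total == 0:  # all in-set scores are exactly zero: fall back to p=0 steps
        hit_weight = hits.astype(float)
        total = float(k)
    running = np.cumsum(hit_weight / total - (~hits) / (N - k))
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _null_es_for_size(
    w_sorted: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES for random same-size sets, vectorised over permutations.

    The running sum is piecewise linear between hit positions, so its
    extrema occur immediately after a hit or immediately before the next
    hit; evaluating those 2*size candidate points suffices.
    """
    N = len(w_sorted)
    idx = np.empty((n_perm, size), dtype=np.int64)
    for p in range(n_perm):
        idx[p] = rng.choice(N, size=size, replace=False)
    idx.sort(axis=1)
    w = w_sorted[idx]
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if np.any(zero):
        w[zero] = 1.0
        totals[zero] = float(size)
    hit_cum = np.cumsum(w, axis=1) / totals
    miss_step = 1.0 / (N - size)
    j = np.arange(size)
    # value right after the j-th hit, and right before it
    after = hit_cum - (idx + 1 - (j + 1)) * miss_step
    before = (hit_cum - w / totals) - (idx - j) * miss_step
    cand = np.concatenate([after, before], axis=1)
    flat = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), flat]


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-set enrichment results plus the permutation bookkeeping."""

    results: pd.DataFrame
    n_perm: int
    seed: int


class GeneSetEnrichment(BaseEstimator):
    """Permutation GSEA over a collection of gene sets.

    Parameters
    ----------
    n_perm : number of random same-size null sets per set size.
    seed : seed for the permutation generator.
    weight_exponent : p in the |score|^p hit increments (1 is the
        standard weighting; 0 gives the unweighted KS statistic).
    min_size, max_size : size band; out-of-band sets are flagged in the
        results but still scored.

    After :meth:`fit`, ``results_`` holds one row per set with columns
    size, n_used, es, nes, p_nominal, fdr_q, fwer, size_flag.
    """

    def __init__(
        self,
        n_perm: int = 1000,
        seed: int = 0,
        weight_exponent: float = 1.0,
        min_size: int = 5,
        max_size: int = 500,
    ):
        self.n_perm = n_perm
        self.seed = seed
        self.weight_exponent = weight_exponent
        self.min_size = min_size
        self.max_size = max_size

    def fit(self, ranked: pd.Series, collection: GeneSetCollection) -> "GeneSetEnrichment":
        if self.n_perm < 10:
            raise ValueError("n_perm must be at least 10")
        ranked = _validate_ranked(ranked)
        if isinstance(collection, dict):
            collection = GeneSetCollection(collection)
        N = len(ranked)
        universe = set(ranked.index)
        rng = np.random.default_rng(self.seed)
        w_sorted = np.abs(ranked.to_numpy(float)) ** self.weight_exponent
        flags = collection.size_flags(self.min_size, self.max_size)

        names, sizes, es_obs = [], [], []
        for name, members in collection.sets.items():
            used = members & universe
            if not used:
                warnings.warn(f"set {name!r} has no genes in the universe; skipped",
                              RuntimeWarning, stacklevel=2)
                continue
            if len(used) > N / 2:
                warnings.warn(f"set {name!r} covers over half the universe",
                              RuntimeWarning, stacklevel=2)
            es, _ = enrichment_score(ranked, used, self.weight_exponent)
            names.append(name)
            sizes.append(len(used))
            es_obs.append(es)
        es_obs = np.asarray(es_obs)

        # one null ES matrix per distinct set size (the null depends only
        # on size); drawn in sorted-size order for determinism
        null_by_size: dict[int, np.ndarray] = {}
        for size in sorted(set(sizes)):
            null_by_size[size] = _null_es_for_size(w_sorted, size, self.n_perm, rng)

        nes_obs = np.empty(len(names))
        p_nom = np.empty(len(names))
        nes_null = np.empty((len(names), self.n_perm))
        for i, (size, es) in enumerate(zip(sizes, es_obs)):
            null = null_by_size[size]
            pos_mean = np.abs(null[null >= 0]).mean() if np.any(null >= 0) else np.nan
            neg_mean = np.abs(null[null < 0]).mean() if np.any(null < 0) else np.nan
            nes_null[i] = np.where(
                null >= 0,
                null / pos_mean if pos_mean and pos_mean > 0 else 0.0,
                null / neg_mean if neg_mean and neg_mean > 0 else 0.0,
            )
            same_sign = null >= 0 if es >= 0 else null < 0
            denom = max(int(same_sign.sum()), 1)
            p_nom[i] = float(np.sum(np.abs(null[same_sign]) >= abs(es))) / denom
            scale = pos_mean if es >= 0 else neg_mean
            nes_obs[i] = es / scale if scale and scale > 0 else 0.0

        fdr = self._fdr(nes_obs, nes_null)
        fwer = self._fwer(nes_obs, nes_null)

        self.results_ = pd.DataFrame(
            {
                "size": [len(collection.sets[n]) for n in names],
                "n_used": sizes,
                "es": es_obs,
                "nes": nes_obs,
                "p_nominal": p_nom,
                "fdr_q": fdr,
                "fwer": fwer,
                "size_flag": [flags[n] for n in names],
            },
            index=pd.Index(names, name="set"),
        )
        self.table_ = EnrichmentTable(self.results_, self.n_perm, self.seed)
        return self

    @staticmethod
    def _fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
        pool = nes_null.ravel()
        q = np.empty_like(nes_obs)
        for i, nes in enumerate(nes_obs):
            if nes >= 0:
                null_side, obs_side = pool[pool >= 0], nes_obs[nes_obs >= 0]
                num = np.mean(null_side >= nes) if null_side.size else 0.0
                den = np.mean(obs_side >= nes) if obs_side.size else 1.0
            else:
                null_side, obs_side = pool[pool < 0], nes_obs[nes_obs < 0]
                num = np.mean(null_side <= nes) if null_side.size else 0.0
                den = np.mean(obs_side <= nes) if obs_side.size else 1.0
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        return q

    @staticmethod
    def _fwer(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
        max_pos = nes_null.max(axis=0)
        min_neg = nes_null.min(axis=0)
        out = np.empty_like(nes_obs)
        for i, nes in enumerate(nes_obs):
            if nes >= 0:
                out[i] = float(np.mean(max_pos >= nes))
            else:
                out[i] = float(np.mean(min_neg <= nes))
        return out


def permute_and_score(
    ranked: pd.Series,
    collection: GeneSetCollection | dict,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Run permutation GSEA; see :class:`GeneSetEnrichment`."""
    model = GeneSetEnrichment(
        n_perm=n_perm,
        seed=seed,
        weight_exponent=weight_exponent,
        min_size=min_size,
        max_size=max_size,
    )
    return model.fit(ranked, collection).results_
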