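"""Phylogenetic community structure: Sørensen similarity and Π_ST.

The Π_ST statistic partitions mean phylogenetic divergence between
distinct species into a within-site component Δ^P_S (averaged over all
co-occurring pairs, pooled across sites) and a total-pool component
Δ^P_T (averaged over all pairs in the pooled species set):

    Π_ST = (Δ^P_T - Δ^P_S) / Δ^P_T

Positive values indicate phylogenetic clustering within sites, negative
values phylogenetic dispersion.  Divergence between two species is the
age of their most recent common ancestor.  Truncating the pair set at a
divergence threshold T and permuting species identities only within the
clades that diverge below T ("partial randomization") isolates the
community structure attributable to recent divergences, so a profile of
Π_ST against T reveals when in time the structure arose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ChronodivError, DomainError, UntestableError
from .tree import Chronogram

__all__ = [
    "OccurrenceMatrix",
    "sorensen",
    "community_summary",
    "delta_means",
    "pi_st",
    "PiStResult",
    "PiStTest",
    "partial_randomization_test",
    "pist_profile",
]

HABITATS = ("inner_reef", "outer_slope")


def round_report(x: float, ndigits: int = 3) -> float:
    """Round half away from zero, the convention used in report tables."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class UndefinedMeanError(ChronodivError, ValueError):
    """No species pair qualifies below the divergence threshold."""


# ----------------------------------------------------------------------
# occurrence data
# ----------------------------------------------------------------------
class OccurrenceMatrix:
    """Binary species × site table with optional site metadata.

    Parameters
    ----------
    presence : DataFrame
        Rows species, columns sites, cells 0/1.
    metadata : DataFrame, optional
        Indexed by site with columns ``island`` and ``habitat``
        (``inner_reef`` / ``outer_slope``).
    """

    def __init__(self, presence: pd.DataFrame, metadata: Optional[pd.DataFrame] = None):
        pres = presence.astype(np.int8)
        vals = pres.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DomainError("presence cells must be 0 or 1")
        if pres.index.duplicated().any() or pres.columns.duplicated().any():
            raise DomainError("duplicate species or site labels")
        self.presence = pres
        if metadata is not None:
            missing = [s for s in pres.columns if s not in metadata.index]
            if missing:
                raise DomainError(f"sites missing from metadata: {missing}")
            metadata = metadata.loc[pres.columns]
        self.metadata = metadata

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_wide_csv(cls, path, metadata_path=None, sep=None) -> "OccurrenceMatrix":
        pres = pd.read_csv(path, index_col=0, sep=sep, engine="python")
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, index_col=0)
        return cls(pres, meta)

    @classmethod
    def from_long_csv(cls, path, metadata_path=None) -> "OccurrenceMatrix":
        long = pd.read_csv(path)
        if long.shape[1] < 2:
            raise DomainError("long format needs columns species,site")
        long.columns = ["species", "site"] + list(long.columns[2:])
        pres = (
            pd.crosstab(long["species"], long["site"]).clip(upper=1).astype(np.int8)
        )
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, index_col=0)
        return cls(pres, meta)

    # -- views ----------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.presence.index]

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.presence.columns]

    def site_set(self, site: str) -> set[str]:
        col = self.presence[site]
        return set(col.index[col == 1].astype(str))

    def occupied(self) -> "OccurrenceMatrix":
        """Restrict to species present in at least one site."""
        keep = self.presence.sum(axis=1) > 0
        return OccurrenceMatrix(self.presence.loc[keep], self.metadata)

    def restrict(self, species=None, sites=None) -> "OccurrenceMatrix":
        pres = self.presence
        if species is not None:
            pres = pres.loc[[s for s in pres.index if s in set(species)]]
        if sites is not None:
            pres = pres[[s for s in pres.columns if s in set(sites)]]
        meta = self.metadata
        if meta is not None:
            meta = meta.loc[pres.columns]
        return OccurrenceMatrix(pres, meta)

    def pool_by_island(self) -> "OccurrenceMatrix":
        """Collapse sites to island species pools (regional-scale units)."""
        if self.metadata is None or "island" not in self.metadata.columns:
            raise DomainError("pooling by island needs site metadata")
        cols = {}
        for island, grp in self.metadata.groupby("island"):
            cols[str(island)] = (
                self.presence[list(grp.index)].max(axis=1).astype(np.int8)
            )
        pres = pd.DataFrame(cols)
        meta = pd.DataFrame(
            {"island": list(pres.columns), "habitat": "pooled"}, index=pres.columns
        )
        return OccurrenceMatrix(pres, meta)

    def pool_by_habitat(self, island: str) -> "OccurrenceMatrix":
        """One island's sites collapsed to inner-reef / outer-slope lists."""
        if self.metadata is None:
            raise DomainError("pooling by habitat needs site metadata")
        grp = self.metadata[self.metadata["island"] == island]
        if grp.empty:
            raise DomainError(f"unknown island {island!r}")
        cols = {}
        for hab, sub in grp.groupby("habitat"):
            cols[str(hab)] = self.presence[list(sub.index)].max(axis=1).astype(np.int8)
        pres = pd.DataFrame(cols)
        meta = pd.DataFrame(
            {"island": island, "habitat": list(pres.columns)}, index=pres.columns
        )
        return OccurrenceMatrix(pres, meta)

    def to_wide_csv(self, path, metadata_path=None) -> None:
        self.presence.to_csv(path)
        if metadata_path is not None and self.metadata is not None:
            self.metadata.to_csv(metadata_path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"OccurrenceMatrix({len(self.presence)} species x "
            f"{self.presence.shape[1]} sites)"
        )


# ----------------------------------------------------------------------
# similarity and summaries
# ----------------------------------------------------------------------
def sorensen(site_a: Iterable[str], site_b: Iterable[str]) -> float:
    """Sørensen similarity 2c/(A+B) of two species sets."""
    a, b = set(site_a), set(site_b)
    if not a and not b:
        raise DomainError("Sørensen similarity of two empty sets is undefined")
    return 2.0 * len(a & b) / (len(a) + len(b))


def _pairwise_sorensen(sets: list[set[str]]) -> list[float]:
    out = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            out.append(sorensen(sets[i], sets[j]))
    return out


def community_summary(occ: OccurrenceMatrix) -> pd.DataFrame:
    """Per island × habitat: site counts, richness, and Sørensen similarity.

    Groups with a single site report similarity as missing.  Each island
    also gets a ``total`` row whose similarity is the mean over
    cross-habitat site pairs.
    """
    if occ.metadata is None:
        raise DomainError("community summary needs site metadata")
    rows = []
    for island, grp in occ.metadata.groupby("island"):
        hab_sets: dict[str, list[set[str]]] = {}
        for hab, sub in grp.groupby("habitat"):
            sets = [occ.site_set(s) for s in sub.index]
            hab_sets[str(hab)] = sets
            rich = np.array([len(s) for s in sets], dtype=float)
            sims = _pairwise_sorensen(sets) if len(sets) > 1 else []
            rows.append(
                {
                    "island": island,
                    "habitat": hab,
                    "n_sites": len(sets),
                    "total_species": len(set().union(*sets)),
                    "mean_richness": float(rich.mean()),
                    "sd_richness": float(rich.std(ddof=1)) if len(rich) > 1 else np.nan,
                    "mean_similarity": float(np.mean(sims)) if sims else np.nan,
                    "sd_similarity": (
                        float(np.std(sims, ddof=1)) if len(sims) > 1 else np.nan
                    ),
                }
            )
        all_sets = [s for sets in hab_sets.values() for s in sets]
        cross = [
            sorensen(sa, sb)
            for ha in hab_sets
            for hb in hab_sets
            if ha < hb
            for sa in hab_sets[ha]
            for sb in hab_sets[hb]
        ]
        rows.append(
            {
                "island": island,
                "habitat": "total",
                "n_sites": len(all_sets),
                "total_species": len(set().union(*all_sets)),
                "mean_richness": float(np.mean([len(s) for s in all_sets])),
                "sd_richness": (
                    float(np.std([len(s) for s in all_sets], ddof=1))
                    if len(all_sets) > 1
                    else np.nan
                ),
                "mean_similarity": float(np.mean(cross)) if cross else np.nan,
                "sd_similarity": float(np.std(cross, ddof=1)) if len(cross) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Δ^P means and Π_ST
# ----------------------------------------------------------------------
def pi_st(delta_S: float, delta_T: float) -> float:
    """Π_ST = (Δ^P_T - Δ^P_S) / Δ^P_T."""
    if delta_T <= 0:
        raise DomainError("delta_T must be positive")
    return (delta_T - delta_S) / delta_T


class _PairIndex:
    """Precomputed pair indices for fast (permuted) Δ^P means.

    Indices refer to positions in the full tip set of the tree, so label
    permutations over the tree translate into index lookups into the full
    divergence matrix.
    """

    def __init__(
        self,
        occ: OccurrenceMatrix,
        tree: Chronogram,
        delta_t_mode: str = "pooled",
    ):
        occ = occ.occupied()
        tips = tree.tips
        pos = {sp: i for i, sp in enumerate(tips)}
        unknown = [sp for sp in occ.species if sp not in pos]
        if unknown:
            raise DomainError(f"species absent from the tree: {sorted(unknown)}")
        self.occ = occ
        self.tree = tree
        self.d = tree.divergence_matrix().to_numpy()
        site_idx = [
            np.array(sorted(pos[sp] for sp in occ.site_set(s)), dtype=int)
            for s in occ.sites
        ]
        ii_s, jj_s = [], []
        for idxs in site_idx:
            if len(idxs) >= 2:
                a, b = np.triu_indices(len(idxs), 1)
                ii_s.append(idxs[a])
                jj_s.append(idxs[b])
        self.ii_S = np.concatenate(ii_s) if ii_s else np.empty(0, dtype=int)
        self.jj_S = np.concatenate(jj_s) if jj_s else np.empty(0, dtype=int)

        pool = np.array(sorted(pos[sp] for sp in occ.species), dtype=int)
        if delta_t_mode == "pooled":
            a, b = np.triu_indices(len(pool), 1)
            self.ii_T = pool[a]
            self.jj_T = pool[b]
        elif delta_t_mode == "between_sites":
            ii_t, jj_t = [], []
            for x in range(len(site_idx)):
                for y in range(x + 1, len(site_idx)):
                    A, B = np.meshgrid(site_idx[x], site_idx[y], indexing="ij")
                    keep = A.ravel() != B.ravel()
                    ii_t.append(A.ravel()[keep])
                    jj_t.append(B.ravel()[keep])
            self.ii_T = np.concatenate(ii_t) if ii_t else np.empty(0, dtype=int)
            self.jj_T = np.concatenate(jj_t) if jj_t else np.empty(0, dtype=int)
        else:
            raise DomainError(f"unknown delta_t_mode {delta_t_mode!r}")

    def deltas(self, threshold: float, perm: Optional[np.ndarray] = None):
        """(Δ^P_S, Δ^P_T) truncated at ``threshold``; NaN when undefined."""
        d = self.d
        if perm is None:
            dS = d[self.ii_S, self.jj_S]
            dT = d[self.ii_T, self.jj_T]
        else:
            dS = d[perm[self.ii_S], perm[self.jj_S]]
            dT = d[perm[self.ii_T], perm[self.jj_T]]
        selS = dS[dS < threshold]
        selT = dT[dT < threshold]
        mS = float(selS.mean()) if len(selS) else np.nan
        mT = float(selT.mean()) if len(selT) else np.nan
        return mS, mT


def delta_means(
    occ: OccurrenceMatrix,
    div: pd.DataFrame | Chronogram,
    threshold: float,
    delta_t_mode: str = "pooled",
) -> tuple[float, float]:
    """Observed (Δ^P_S, Δ^P_T) at a divergence threshold, in Myr.

    Only unordered distinct-species pairs with divergence strictly below
    ``threshold`` qualify.  Δ^P_S pools all (site, co-occurring pair)
    instances with equal weight; Δ^P_T averages over the pooled species
    set of the analysis (or cross-site pairs with
    ``delta_t_mode='between_sites'``).
    """
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    if isinstance(div, Chronogram):
        div = div.divergence_matrix()
    occ = occ.occupied()
    labels = [str(x) for x in div.index]
    pos = {sp: i for i, sp in enumerate(labels)}
    unknown = [sp for sp in occ.species if sp not in pos]
    if unknown:
        raise DomainError(f"species absent from the divergence matrix: {sorted(unknown)}")
    d = div.to_numpy()

    inst = []
    for s in occ.sites:
        idxs = np.array(sorted(pos[sp] for sp in occ.site_set(s)), dtype=int)
        if len(idxs) >= 2:
            a, b = np.triu_indices(len(idxs), 1)
            inst.append(d[idxs[a], idxs[b]])
    dS = np.concatenate(inst) if inst else np.empty(0)

    pool = np.array(sorted(pos[sp] for sp in occ.species), dtype=int)
    if delta_t_mode == "pooled":
        a, b = np.triu_indices(len(pool), 1)
        dT = d[pool[a], pool[b]]
    elif delta_t_mode == "between_sites":
        cross = []
        site_idx = [
            np.array(sorted(pos[sp] for sp in occ.site_set(s)), dtype=int)
            for s in occ.sites
        ]
        for x in range(len(site_idx)):
            for y in range(x + 1, len(site_idx)):
                A, B = np.meshgrid(site_idx[x], site_idx[y], indexing="ij")
                keep = A.ravel() != B.ravel()
                cross.append(d[A.ravel()[keep], B.ravel()[keep]])
        dT = np.concatenate(cross) if cross else np.empty(0)
    else:
        raise DomainError(f"unknown delta_t_mode {delta_t_mode!r}")

    selS = dS[dS < threshold]
    selT = dT[dT < threshold]
    if len(selS) == 0 or len(selT) == 0:
        raise UndefinedMeanError(f"no species pair diverges below {threshold} Myr")
    return float(selS.mean()), float(selT.mean())


# ----------------------------------------------------------------------
# the permutation test
# ----------------------------------------------------------------------
@dataclass
class PiStResult:
    """Observed Π_ST with its partial-randomization null at one threshold."""

    threshold: float
    obs_delta_S: float
    obs_delta_T: float
    obs_pi: float
    null_mean: float
    null_sd: float
    ci_low: float
    ci_high: float
    p_lower: float
    p_upper: float
    replicates: int
    seed: Optional[int] = None
    untestable: bool = False
    null_values: Optional[np.ndarray] = field(default=None, repr=False)

    def summary(self) -> str:
        flag = "  [untestable: all randomization blocks are singletons]" if self.untestable else ""
        return (
            f"Pi_ST at threshold {self.threshold:g} Myr{flag}\n"
            f"  obs: Delta_S = {self.obs_delta_S:.3f}  Delta_T = "
            f"{self.obs_delta_T:.3f}  Pi_ST = {self.obs_pi:.3f}\n"
            f"  null (R={self.replicates}): mean = {self.null_mean:.3f}  "
            f"SD = {self.null_sd:.3f}  CI = [{self.ci_low:.3f}, {self.ci_high:.3f}]\n"
            f"  one-sided p: obs<exp {self.p_lower:.3f}   obs>exp {self.p_upper:.3f}"
        )

    def to_row(self) -> dict:
        return {
            "threshold": self.threshold,
            "delta_S": self.obs_delta_S,
            "delta_T": self.obs_delta_T,
            "pi_st": self.obs_pi,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "replicates": self.replicates,
            "untestable": self.untestable,
        }


def _block_permutation(blocks: list[np.ndarray], n: int, rng) -> np.ndarray:
    perm = np.arange(n)
    for blk in blocks:
        if len(blk) > 1:
            perm[blk] = blk[rng.permutation(len(blk))]
    return perm


class PiStTest:
    """Partial-randomization test of phylogenetic community structure.

    Model object in the fit/results style: construction binds the data
    (occurrence matrix + chronogram) and configuration; :meth:`fit` runs
    the Monte-Carlo null and returns a :class:`PiStResult`.

    The null permutes species identities uniformly within each maximal
    clade whose crown age lies below the divergence threshold, leaving
    deeper tree structure fixed (``null_mode='partial'``).  With
    ``null_mode='truncate_only'`` the whole tip set is shuffled and only
    the pair-set truncation at the threshold remains.
    """

    def __init__(
        self,
        occ: OccurrenceMatrix,
        tree: Chronogram,
        threshold: float,
        delta_t_mode: str = "pooled",
        null_mode: str = "partial",
    ):
        if threshold <= 0:
            raise DomainError("threshold must be positive")
        if null_mode not in ("partial", "truncate_only"):
            raise DomainError(f"unknown null_mode {null_mode!r}")
        self.threshold = float(threshold)
        self.null_mode = null_mode
        self.tree = tree
        self._pairs = _PairIndex(occ, tree, delta_t_mode=delta_t_mode)
        pos = {sp: i for i, sp in enumerate(tree.tips)}
        if null_mode == "partial":
            blocks = tree.clades_below_threshold(self.threshold)
        else:
            blocks = [set(tree.tips)]
        self.blocks = [
            np.array(sorted(pos[sp] for sp in blk), dtype=int) for blk in blocks
        ]

    def fit(self, reps: int = 999, seed: Optional[int] = None) -> PiStResult:
        if reps < 1:
            raise DomainError("reps must be >= 1")
        T = self.threshold
        obs_S, obs_T = self._pairs.deltas(T)
        if np.isnan(obs_S) or np.isnan(obs_T) or obs_T <= 0:
            raise UndefinedMeanError(
                f"no qualifying species pair below {T} Myr; Pi_ST undefined"
            )
        obs_pi = pi_st(obs_S, obs_T)
        untestable = all(len(b) <= 1 for b in self.blocks)
        if untestable:
            warnings.warn(
                f"threshold {T} Myr: all randomization blocks are singletons; "
                "the null is degenerate and the test uninformative",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        n = self.tree.n
        null = np.full(reps, np.nan)
        for r in range(reps):
            perm = _block_permutation(self.blocks, n, rng)
            mS, mT = self._pairs.deltas(T, perm)
            if not np.isnan(mS) and not np.isnan(mT) and mT > 0:
                null[r] = pi_st(mS, mT)
        valid = null[~np.isnan(null)]
        R = len(valid)
        if R == 0:
            raise UndefinedMeanError("every null replicate left the mean undefined")
        p_upper = (np.sum(valid >= obs_pi) + 1.0) / (R + 1.0)
        p_lower = (np.sum(valid <= obs_pi) + 1.0) / (R + 1.0)
        return PiStResult(
            threshold=T,
            obs_delta_S=obs_S,
            obs_delta_T=obs_T,
            obs_pi=obs_pi,
            null_mean=float(valid.mean()),
            null_sd=float(valid.std(ddof=1)) if R > 1 else 0.0,
            ci_low=float(np.quantile(valid, 0.025)),
            ci_high=float(np.quantile(valid, 0.975)),
            p_lower=float(p_lower),
            p_upper=float(p_upper),
            replicates=R,
            seed=seed,
            untestable=untestable,
            null_values=valid,
        )


def partial_randomization_test(
    occ: OccurrenceMatrix,
    tree: Chronogram,
    threshold: float,
    reps: int = 999,
    seed: Optional[int] = None,
    delta_t_mode: str = "pooled",
    null_mode: str = "partial",
) -> PiStResult:
    """Functional façade over :class:`PiStTest`."""
    return PiStTest(
        occ, tree, threshold, delta_t_mode=delta_t_mode, null_mode=null_mode
    ).fit(reps=reps, seed=seed)


def pist_profile(
    occ: OccurrenceMatrix,
    tree: Chronogram,
    thresholds: Sequence[float],
    reps: int = 999,
    seed: Optional[int] = None,
    delta_t_mode: str = "pooled",
    null_mode: str = "partial",
) -> tuple[pd.DataFrame, list[PiStResult]]:
    """Π_ST tested at an ascending grid of divergence thresholds.

    Deterministic for a given seed: each threshold gets an independent
    child seed.  Thresholds at which the statistic or the null is
    undefined are reported with missing values.
    """
    ths = list(thresholds)
    if any(ths[i] >= ths[i + 1] for i in range(len(ths) - 1)):
        raise DomainError("thresholds must be strictly ascending")
    seeds = np.random.SeedSequence(seed).spawn(len(ths))
    rows, results = [], []
    for T, ss in zip(ths, seeds):
        child_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = PiStTest(
                    occ, tree, T, delta_t_mode=delta_t_mode, null_mode=null_mode
                ).fit(reps=reps, seed=child_seed)
            rows.append(res.to_row())
            results.append(res)
        except UndefinedMeanError:
            rows.append(
                {
                    "threshold": T,
                    "delta_S": np.nan,
                    "delta_T": np.nan,
                    "pi_st": np.nan,
                    "null_mean": np.nan,
                    "null_sd": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_lower": np.nan,
                    "p_upper": np.nan,
                    "replicates": 0,
                    "untestable": True,
                }
            )
            results.append(None)
    return pd.DataFrame(rows), results


REGIONAL_THRESHOLDS = tuple(float(x) for x in range(5, 55, 5))
LOCAL_THRESHOLDS = tuple(float(x) for x in range(10, 60, 10))
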