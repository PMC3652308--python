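"""Over-representation analysis of gene sets among changed genes.

For a universe of N genes, a set of R genes and n changed genes with r of
them in the set, the enrichment z-score standardises r by its
hypergeometric moments:

    z = (r - nR/N) / sqrt( n (R/N) (1 - R/N) (1 - (n-1)/(N-1)) )

Permutation p-values resample the changed list from the universe (add-one
estimator).  A set is reported when z >= 1.96 and it contains at least 3
changed genes; Benjamini-Hochberg q-values on the permutation p are
reported alongside but never used for gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "ora_z",
    "permutation_p",
    "enrich",
    "rank_report",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe."""

    sets: dict[str, list[str]]
    background: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bg = set(self.background)
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValueError(f"gene set {name} is empty")
            extra = set(members) - bg
            if extra:
                raise ValueError(
                    f"gene set {name} has members outside the background: {sorted(extra)[:5]}"
                )

    @classmethod
    def from_gmt(cls, path, background=None) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                name, _desc, *genes = parts
                sets[name] = [g for g in genes if g]
        if background is None:
            background = sorted({g for members in sets.values() for g in members})
        return cls(sets=sets, background=list(background))

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                fh.write("\t".join([name, "na", *self.sets[name]]) + "\n")


def ora_z(N: int, R: int, n: int, r: int) -> float:
    """Hypergeometric-moment standardisation of the overlap count r."""
    if N <= 0:
        raise ValueError("universe size N must be positive")
    if not (0 <= R <= N and 0 <= n <= N):
        raise ValueError("need R <= N and n <= N")
    if not 0 <= r <= min(n, R):
        raise ValueError("overlap r must satisfy 0 <= r <= min(n, R)")
    p = R / N
    fpc = 1.0 - (n - 1.0) / (N - 1.0) if N > 1 else 0.0
    var = n * p * (1.0 - p) * fpc
    if var <= 0:
        return 0.0
    return float((r - n * p) / np.sqrt(var))


def permutation_p(
    set_genes,
    changed_genes,
    background,
    n_perm: int = 2000,
    seed: int = 0,
) -> float:
    """Permutation p for one set: resample the changed list from background.

    perm_p = (1 + #{permutation z >= observed z}) / (n_perm + 1).
    """
    background = list(background)
    changed = set(changed_genes)
    members = set(set_genes)
    N, R = len(background), len(members)
    if len(changed) > N:
        raise ValueError("more changed genes than background genes")
    changed &= set(background)
    n = len(changed)
    obs_z = ora_z(N, R, n, len(changed & members))
    rng = np.random.default_rng(seed)
    in_set = np.fromiter((g in members for g in background), dtype=bool, count=N)
    count = 0
    for _ in range(n_perm):
        draw = rng.choice(N, size=n, replace=False)
        r_perm = int(in_set[draw].sum())
        if ora_z(N, R, n, r_perm) >= obs_z:
            count += 1
    return (1 + count) / (n_perm + 1)


def enrich(
    collection: GeneSetCollection,
    changed_genes,
    n_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every set: overlap, z, permutation p and BH q.

    One shared null ensemble of resampled changed lists serves all sets
    (each permutation draws one changed list and scores every set against
    it), so q-values are comparable across sets.
    """
    background = list(collection.background)
    N = len(background)
    changed = [g for g in dict.fromkeys(changed_genes) if g in set(background)]
    n = len(changed)
    names = sorted(collection.sets)
    member_mask = np.zeros((len(names), N), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(background)}
    for k, name in enumerate(names):
        for g in collection.sets[name]:
            member_mask[k, gene_pos[g]] = True
    changed_idx = np.array([gene_pos[g] for g in changed], dtype=int)
    R = member_mask.sum(axis=1)
    r_obs = member_mask[:, changed_idx].sum(axis=1) if n else np.zeros(len(names), int)
    z_obs = np.array([ora_z(N, int(R[k]), n, int(r_obs[k])) for k in range(len(names))])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names), dtype=int)
    for _ in range(n_perm):
        draw = rng.choice(N, size=n, replace=False)
        r_perm = member_mask[:, draw].sum(axis=1)
        for k in range(len(names)):
            if ora_z(N, int(R[k]), n, int(r_perm[k])) >= z_obs[k]:
                exceed[k] += 1
    perm_p = (1 + exceed) / (n_perm + 1)
    bh_q = multipletests(perm_p, method="fdr_bh")[1] if len(names) else perm_p
    out = pd.DataFrame(
        {
            "set": names,
            "N": N,
            "R": R,
            "n": n,
            "r": r_obs,
            "z_score": z_obs,
            "perm_p": perm_p,
            "bh_q": bh_q,
        }
    ).set_index("set")
    return out


def rank_report(
    results: pd.DataFrame, z_cutoff: float = 1.96, min_genes: int = 3
) -> pd.DataFrame:
    """Filter by the z and changed-gene-count gates and rank.

    Sort order: z descending, overlap r descending, set name.  The BH q
    column is carried through but does not gate.
    """
    out = results.reset_index()
    name_col = out.columns[0]
    out["reported"] = (out["z_score"] >= z_cutoff) & (out["r"] >= min_genes)
    out = out[out["reported"]]
    out = out.sort_values(
        ["z_score", "r", name_col], ascending=[False, False, True], kind="mergesort"
    )
    return out.set_index(name_col)
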