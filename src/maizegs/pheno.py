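"""Phenotype adjustment across environments and trait summaries.

Multi-environment trial records (genotype x environment x replicate, trait
values in mg/kg) are reduced to one adjusted mean per genotype via a
two-way additive fixed-effects model

    y_ik = mu + env_i + gen_k + e_ik

fitted by least squares with sum-to-zero environment constraints.  The
least-squares mean of genotype k is its prediction at the average
environment, which collapses to the raw genotype mean in balanced designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

GENOTYPE, ENVIRONMENT, REPLICATE, VALUE = "genotype", "environment", "replicate", "value"


class PhenotypeError(ValueError):
    pass


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = {GENOTYPE, ENVIRONMENT, VALUE} - set(records.columns)
    if missing:
        raise PhenotypeError(f"phenotype table lacks columns {sorted(missing)}")
    if not np.isfinite(records[VALUE].to_numpy(dtype=float)).all():
        raise PhenotypeError("phenotype values must be finite")
    return records


def replicate_means(records: pd.DataFrame) -> pd.DataFrame:
    """Average replicates within each genotype x environment cell.

    Returns a long table with one record per observed cell (replicate
    column dropped).  With a single replicate this is an identity on the
    (genotype, environment, value) content.
    """
    _check_records(records)
    out = (
        records.groupby([GENOTYPE, ENVIRONMENT], sort=False, observed=True)[VALUE]
        .mean()
        .reset_index()
    )
    return out


def ls_means(records: pd.DataFrame) -> pd.Series:
    """Least-squares genotype means across environments.

    Fits ``value ~ genotype + environment`` by ordinary least squares with
    sum-to-zero environment effects and reports ``mu + gen_k`` per
    genotype.  Replicates, if present, are first averaged per cell.
    Requires a connected genotype x environment incidence; a disconnected
    design is rejected with the offending blocks named.

    Returns a Series indexed by genotype id, in order of first appearance.
    """
    cells = replicate_means(records)
    geno_codes, geno_ids = pd.factorize(cells[GENOTYPE])
    env_codes, env_ids = pd.factorize(cells[ENVIRONMENT])
    n_g, n_e = len(geno_ids), len(env_ids)
    y = cells[VALUE].to_numpy(dtype=float)

    _check_connected(geno_codes, env_codes, geno_ids, env_ids)

    if n_e == 1:
        vals = pd.Series(y).groupby(geno_codes).mean()
        return pd.Series(vals.to_numpy(), index=pd.Index(geno_ids, name=GENOTYPE),
                         name="lsmean")

    # Design: intercept + genotype dummies (first genotype as reference)
    # + sum-to-zero environment contrasts (last environment dropped,
    # its rows coded -1).
    n_obs = len(y)
    X = np.zeros((n_obs, 1 + (n_g - 1) + (n_e - 1)))
    X[:, 0] = 1.0
    for k in range(1, n_g):
        X[geno_codes == k, k] = 1.0
    for i in range(n_e - 1):
        X[env_codes == i, n_g + i] = 1.0
    X[env_codes == n_e - 1, n_g:] = -1.0

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = beta[0]
    gen = np.concatenate([[0.0], beta[1:n_g]])
    lsm = mu + gen  # env contribution is zero at the average environment
    return pd.Series(lsm, index=pd.Index(geno_ids, name=GENOTYPE), name="lsmean")


def _check_connected(geno_codes, env_codes, geno_ids, env_ids) -> None:
    n_g, n_e = len(geno_ids), len(env_ids)
    # bipartite graph: genotypes 0..n_g-1, environments n_g..n_g+n_e-1
    rows = np.concatenate([geno_codes, env_codes + n_g])
    cols = np.concatenate([env_codes + n_g, geno_codes])
    data = np.ones(len(rows))
    graph = coo_matrix((data, (rows, cols)), shape=(n_g + n_e, n_g + n_e))
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        blocks = []
        for c in range(n_comp):
            gs = [str(g) for g, l in zip(geno_ids, labels[:n_g]) if l == c]
            es = [str(e) for e, l in zip(env_ids, labels[n_g:]) if l == c]
            blocks.append(f"(genotypes {gs[:4]}..., environments {es})")
        raise PhenotypeError(
            "genotype x environment design is disconnected; blocks: "
            + "; ".join(blocks)
        )


def location_correlations(records: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations of genotype values between locations.

    Replicates are averaged per cell first; correlations use genotypes
    observed in both locations (pairwise-complete).  Pairs with fewer than
    ``min_shared`` shared genotypes are reported as NaN.
    """
    cells = replicate_means(records)
    wide = cells.pivot(index=GENOTYPE, columns=ENVIRONMENT, values=VALUE)
    envs = list(wide.columns)
    out = pd.DataFrame(np.eye(len(envs)), index=envs, columns=envs)
    for i, a in enumerate(envs):
        for j in range(i + 1, len(envs)):
            b = envs[j]
            both = wide[[a, b]].dropna()
            if len(both) < min_shared:
                r = np.nan
            else:
                x, z = both[a].to_numpy(), both[b].to_numpy()
                if x.std() == 0 or z.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, z)[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


@dataclass
class TraitSummary:
    n: int
    mean: float
    minimum: float
    maximum: float
    sd: float
    n_above: int
    pct_above: float
    threshold: float


def summarize(means: pd.Series, threshold: float = 33.0) -> TraitSummary:
    """Trait summary over adjusted means: mean, range, sample SD (n-1),
    and the count/percent of genotypes reaching ``threshold`` (inclusive;
    the biofortification target for kernel Zn is 33 mg/kg)."""
    vals = np.asarray(means, dtype=float)
    if vals.size == 0:
        raise PhenotypeError("cannot summarize an empty set of means")
    n_above = int(np.sum(vals >= threshold))
    return TraitSummary(
        n=vals.size,
        mean=float(vals.mean()),
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_above=n_above,
        pct_above=100.0 * n_above / vals.size,
        threshold=threshold,
    )
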