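"""Synthetic maize-population generator.

Emulates the population designs that genomic-prediction experiments on kernel
micronutrient traits are run on, without any data download:

* a diverse inbred association panel -- fully homozygous lines with a
  U-shaped allele-frequency spectrum (Beta(0.158, 0.158) by default, which
  puts ~65% of markers below MAF 0.05 and a mean MAF near 0.09, the regime
  typical of GBS calls on tropical maize panels);
* doubled-haploid (DH) biparental populations -- each line is a doubled
  F1 gamete, with crossovers drawn under a Haldane (no-interference) model
  from per-chromosome genetic map lengths;
* dominant presence/absence marker derivatives of codominant SNPs
  (rAmpSeq-style tags);
* random missingness at a target rate (GBS data average ~29% missing
  before filtering);
* multi-environment phenotypes with purely additive architecture at a
  controlled narrow-sense heritability, on a kernel-Zn-like scale
  (baseline ~26 mg/kg).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geno import CODOMINANT, DOMINANT, GenotypeMatrix, GenotypeError


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Configuration for one synthetic dataset.

    ``maf_spectrum`` gives the (a, b) shape parameters of the Beta prior
    on panel allele frequencies.  ``h2_target`` is the narrow-sense
    heritability targeted at the level of genotype means across
    environments (the scale on which prediction is evaluated).
    ``env_effect_sd`` is the SD of environment main effects in mg/kg.
    """

    pop_type: str = "panel"
    n_ind: int = 236
    n_chrom: int = 10
    markers_per_chrom: int = 200
    map_length_cM: float = 150.0
    maf_spectrum: tuple[float, float] = (0.158, 0.158)
    n_qtl: int = 40
    h2_target: float = 0.75
    n_env: int = 3
    n_rep: int = 1
    env_effect_sd: float = 2.0
    baseline: float = 26.0
    effect_sd: float = 1.0
    missing_rate_target: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_type not in ("panel", "dh"):
            raise SimError(f"pop_type must be 'panel' or 'dh', got {self.pop_type!r}")
        for name in ("n_ind", "n_chrom", "markers_per_chrom", "n_env", "n_rep"):
            if getattr(self, name) < 1:
                raise SimError(f"{name} must be a positive count")
        if not 0.0 < self.h2_target <= 1.0:
            raise SimError("h2_target must lie in (0, 1]; use n_qtl=0 for a null trait")
        if self.n_qtl < 0 or self.n_qtl > self.n_markers:
            raise SimError(
                f"n_qtl={self.n_qtl} outside [0, {self.n_markers} total markers]"
            )
        if not 0.0 <= self.missing_rate_target < 1.0:
            raise SimError("missing_rate_target must lie in [0, 1)")
        if self.map_length_cM < 0:
            raise SimError("map_length_cM must be non-negative")
        a, b = self.maf_spectrum
        if a <= 0 or b <= 0:
            raise SimError("maf_spectrum shape parameters must be positive")

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom


@dataclass
class TrueArchitecture:
    """Ground-truth additive architecture behind a simulated trait."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    residual_sd: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "qtl_indices": [int(i) for i in self.qtl_indices],
            "qtl_effects": [float(e) for e in self.qtl_effects],
            "true_breeding_values": [float(v) for v in self.true_breeding_values],
            "residual_sd": float(self.residual_sd),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _marker_map(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced marker positions (cM) on each chromosome."""
    chrom = np.repeat(np.arange(1, config.n_chrom + 1), config.markers_per_chrom)
    within = (np.arange(config.markers_per_chrom) + 0.5) / config.markers_per_chrom
    pos = np.tile(within * config.map_length_cM, config.n_chrom)
    return chrom, pos


def simulate_panel(config: SimConfig) -> GenotypeMatrix:
    """Simulate a fully homozygous association panel.

    Each marker's allele frequency is drawn from the Beta spectrum; each
    inbred line then carries dosage 2 with that probability, else 0.
    Loci are independent (no LD) unless correlated draws are layered on
    externally; see :func:`simulate_panel_blocks` for a haplotype-block
    variant.
    """
    if config.pop_type != "panel":
        raise SimError("simulate_panel requires pop_type='panel'")
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    a, b = config.maf_spectrum
    freqs = rng.beta(a, b, size=m)
    hom_alt = rng.random((config.n_ind, m)) < freqs
    dosages = np.where(hom_alt, 2.0, 0.0)
    chrom, pos = _marker_map(config)
    return GenotypeMatrix(
        line_ids=np.array([f"L{i:04d}" for i in range(config.n_ind)], dtype=object),
        marker_ids=np.array([f"S{j:05d}" for j in range(m)], dtype=object),
        dosages=dosages,
        marker_class=CODOMINANT,
        chrom=chrom,
        pos=pos,
    )


def simulate_panel_blocks(config: SimConfig, block_size: int = 20) -> GenotypeMatrix:
    """Panel variant with haplotype-block LD: markers within a block share
    one of two block haplotypes per line, so nearby markers are highly
    correlated.  Used to study marker-density plateaus, which require LD."""
    if config.pop_type != "panel":
        raise SimError("simulate_panel_blocks requires pop_type='panel'")
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    a, b = config.maf_spectrum
    dosages = np.empty((config.n_ind, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        width = stop - start
        hap1 = (rng.random(width) < 0.5).astype(float) * 2.0
        hap2 = np.where(rng.random(width) < 0.8, 2.0 - hap1, hap1)
        block_freq = rng.beta(a, b)
        pick = rng.random(config.n_ind) < block_freq
        dosages[:, start:stop] = np.where(pick[:, None], hap1, hap2)
    chrom, pos = _marker_map(config)
    return GenotypeMatrix(
        line_ids=np.array([f"L{i:04d}" for i in range(config.n_ind)], dtype=object),
        marker_ids=np.array([f"S{j:05d}" for j in range(m)], dtype=object),
        dosages=dosages,
        marker_class=CODOMINANT,
        chrom=chrom,
        pos=pos,
    )


def simulate_dh(
    config: SimConfig,
    parent1: np.ndarray,
    parent2: np.ndarray,
) -> GenotypeMatrix:
    """Simulate a doubled-haploid population from two inbred parents.

    ``parent1``/``parent2`` are dosage vectors in {0, 2} over the marker
    map implied by ``config`` (length n_chrom * markers_per_chrom).  Each
    DH line is one recombinant F1 gamete, doubled: per chromosome the
    number of crossovers is Poisson(map_length_cM / 100) (Haldane,
    no interference), crossover positions uniform on the map, and the
    gamete alternates parental haplotypes across breakpoints starting from
    a fair coin.  Output dosages are 0/2; only markers where the parents
    differ segregate.
    """
    if config.pop_type != "dh":
        raise SimError("simulate_dh requires pop_type='dh'")
    p1 = np.asarray(parent1, dtype=float).ravel()
    p2 = np.asarray(parent2, dtype=float).ravel()
    m = config.n_markers
    if len(p1) != m or len(p2) != m:
        raise SimError(f"parent haplotypes must have length {m}")
    for name, p in (("parent1", p1), ("parent2", p2)):
        if not np.isin(p[~np.isnan(p)], (0.0, 2.0)).all():
            raise SimError(f"{name} is not fully homozygous (dosages must be 0 or 2)")
    rng = np.random.default_rng(config.seed)
    chrom, pos = _marker_map(config)
    hap1 = p1 / 2.0
    hap2 = p2 / 2.0

    gametes = np.empty((config.n_ind, m))
    for c in range(1, config.n_chrom + 1):
        sel = chrom == c
        cm = pos[sel]
        L = config.map_length_cM
        for i in range(config.n_ind):
            n_xo = rng.poisson(L / 100.0)
            breaks = np.sort(rng.uniform(0.0, L, size=n_xo))
            # parental phase at each marker: start coin, flip at each break
            phase = (np.searchsorted(breaks, cm) + rng.integers(0, 2)) % 2
            gametes[i, sel] = np.where(phase == 0, hap1[sel], hap2[sel])
    dosages = 2.0 * gametes
    return GenotypeMatrix(
        line_ids=np.array([f"DH{i:04d}" for i in range(config.n_ind)], dtype=object),
        marker_ids=np.array([f"S{j:05d}" for j in range(m)], dtype=object),
        dosages=dosages,
        marker_class=CODOMINANT,
        chrom=chrom,
        pos=pos,
    )


def to_dominant(geno: GenotypeMatrix, seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Collapse codominant dosages to dominant presence/absence tags.

    Per marker, one allele is designated "tag present" (fair coin under
    ``seed``); lines carrying at least one copy of that allele score 1,
    others 0.  Missing stays missing.  On fully inbred input (dosages in
    {0, 2}) the collapse loses only the allele labeling.
    """
    if geno.marker_class == DOMINANT:
        raise GenotypeError("input is already dominant")
    rng = np.random.default_rng(seed)
    present_is_alt = rng.random(geno.n_markers) < 0.5
    d = geno.dosages
    presence = np.where(present_is_alt, d >= 1.0, d <= 1.0).astype(float)
    presence[np.isnan(d)] = np.nan
    return GenotypeMatrix(
        line_ids=geno.line_ids,
        marker_ids=np.array([f"{mid}_tag" for mid in geno.marker_ids], dtype=object),
        dosages=presence,
        marker_class=DOMINANT,
        chrom=geno.chrom,
        pos=geno.pos,
    )


def inject_missing(
    geno: GenotypeMatrix, rate: float, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Mask each cell independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise SimError(f"missing rate must lie in [0, 1), got {rate}")
    if rate == 0.0:
        return replace(geno, dosages=geno.dosages.copy())
    rng = np.random.default_rng(seed)
    d = geno.dosages.copy()
    d[rng.random(d.shape) < rate] = np.nan
    return replace(geno, dosages=d)


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, TrueArchitecture]:
    """Simulate multi-environment phenotypes with additive architecture.

    QTL are sampled without replacement from the markers; effects are
    N(0, effect_sd^2); the true breeding value of a line is its centered
    QTL dosages times the effects.  The plot-level residual SD is set
    analytically so that at the level of genotype means across the
    n_env * n_rep observations,

        Var(TBV) / (Var(TBV) + sigma_e^2 / (n_env * n_rep)) = h2_target

    using the realized Var(TBV).  Environment main effects are drawn once
    per environment and shared by all genotypes.  Records are returned as
    a long table (genotype, environment, replicate, value) in mg/kg.
    """
    if not 0.0 < config.h2_target <= 1.0:
        raise SimError("h2_target must lie in (0, 1]")
    if config.n_qtl > geno.n_markers:
        raise SimError("n_qtl exceeds available markers")
    rng = np.random.default_rng(config.seed + 1_000_003)
    n, m = geno.n_lines, geno.n_markers
    if np.isnan(geno.dosages).any():
        raise SimError("simulate phenotypes on complete (pre-missingness) genotypes")

    if config.n_qtl == 0:
        qtl_idx = np.array([], dtype=int)
        effects = np.array([])
        tbv = np.zeros(n)
    else:
        qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
        # avoid monomorphic QTL where possible: they carry no signal
        mono = np.ptp(geno.dosages[:, qtl_idx], axis=0) == 0
        if mono.any():
            poly = np.flatnonzero(np.ptp(geno.dosages, axis=0) > 0)
            pool = np.setdiff1d(poly, qtl_idx)
            n_swap = min(int(mono.sum()), len(pool))
            if n_swap:
                swap_in = rng.choice(pool, size=n_swap, replace=False)
                qtl_idx[np.flatnonzero(mono)[:n_swap]] = swap_in
                qtl_idx = np.sort(qtl_idx)
        effects = rng.normal(0.0, config.effect_sd, size=config.n_qtl)
        Q = geno.dosages[:, qtl_idx]
        Qc = Q - Q.mean(axis=0)
        tbv = Qc @ effects

    var_tbv = float(np.var(tbv))
    n_obs = config.n_env * config.n_rep
    if var_tbv == 0.0:
        # null trait (n_qtl=0 or monomorphic QTL): pure noise at a
        # typical kernel-Zn phenotypic SD of ~3.5 mg/kg per genotype mean
        resid_sd = 3.5 * np.sqrt(n_obs)
    elif config.h2_target >= 1.0:
        resid_sd = 0.0
    else:
        resid_sd = float(
            np.sqrt(var_tbv * (1.0 / config.h2_target - 1.0) * n_obs)
        )

    env_effects = rng.normal(0.0, config.env_effect_sd, size=config.n_env)
    records = []
    for e in range(config.n_env):
        for r in range(config.n_rep):
            noise = rng.normal(0.0, resid_sd, size=n) if resid_sd > 0 else np.zeros(n)
            vals = config.baseline + env_effects[e] + tbv + noise
            records.append(
                pd.DataFrame(
                    {
                        "genotype": geno.line_ids,
                        "environment": f"E{e + 1}",
                        "replicate": r + 1,
                        "value": vals,
                    }
                )
            )
    table = pd.concat(records, ignore_index=True)
    arch = TrueArchitecture(
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        true_breeding_values=tbv,
        residual_sd=resid_sd,
    )
    return table, arch


def write_phenotypes(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a YAML/JSON-style mapping."""
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise SimError(f"unknown SimConfig fields: {sorted(unknown)}")
    if "maf_spectrum" in d:
        d = dict(d, maf_spectrum=tuple(d["maf_spectrum"]))
    return SimConfig(**d)
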