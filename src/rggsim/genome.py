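"""Founder genomes, meiosis, line development and genomic relationships.

The genetic architecture is a Fisher infinitesimal approximation for soybean
seed yield: biallelic loci on a 20-chromosome linkage map (2145.5 cM by
default), a subset of which act as additive QTL.  Founders are fully inbred
purelines (optionally loaded from a user genotype matrix); crossing and
selfing follow Mendelian segregation with Poisson crossovers and no
interference (Haldane map function).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "FounderPopulation",
    "Individual",
    "QTLEffectSet",
    "build_genetic_map",
    "load_genetic_map",
    "simulate_founders",
    "load_founders",
    "sample_qtl_effects",
    "gametes_batch",
    "cross",
    "self_progeny",
    "develop_line",
    "develop_lines_batch",
    "genomic_relationship",
]


class ConfigurationError(ValueError):
    """Raised when simulation settings are inconsistent."""


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Linkage map: chromosome lengths (cM), ordered locus positions, QTL flags.

    ``positions`` is a list of arrays (one per chromosome, strictly increasing,
    in cM).  ``qtl_mask`` flags QTL among the concatenated loci.
    """

    chrom_lengths: np.ndarray          # (n_chrom,) in cM
    positions: list                    # list of (l_c,) arrays
    qtl_mask: np.ndarray               # (n_loci,) bool

    def __post_init__(self):
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=float)
        self.qtl_mask = np.asarray(self.qtl_mask, dtype=bool)
        counts = [len(p) for p in self.positions]
        self._offsets = np.concatenate([[0], np.cumsum(counts)])
        for c, p in enumerate(self.positions):
            if np.any(np.diff(p) <= 0):
                raise ConfigurationError(f"locus positions not strictly increasing on chromosome {c}")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)

    @property
    def n_loci(self) -> int:
        return int(self._offsets[-1])

    @property
    def total_cM(self) -> float:
        return float(self.chrom_lengths.sum())

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_mask.sum())

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.qtl_mask)

    def chrom_slice(self, c: int) -> slice:
        return slice(int(self._offsets[c]), int(self._offsets[c + 1]))


def build_genetic_map(n_chrom: int = 20, total_cM: float = 2145.5,
                      loci_per_chrom_range: tuple = (204, 349),
                      n_qtl: int = 1000, rng: np.random.Generator | None = None) -> GeneticMap:
    """Build a random linkage map with ``n_qtl`` loci flagged as QTL.

    Chromosome lengths are proportional to their locus counts and sum exactly
    to ``total_cM``; QTL are drawn uniformly among loci with at least one per
    chromosome.
    """
    rng = np.random.default_rng(rng)
    lo, hi = loci_per_chrom_range
    if lo < 1 or hi < lo:
        raise ConfigurationError("invalid loci_per_chrom_range")
    counts = rng.integers(lo, hi + 1, size=n_chrom)
    n_loci = int(counts.sum())
    if n_qtl > n_loci:
        raise ConfigurationError(f"n_qtl={n_qtl} exceeds total loci {n_loci}")
    if n_qtl < n_chrom:
        raise ConfigurationError("need at least one QTL per chromosome")
    lengths = total_cM * counts / counts.sum()
    positions = []
    for c in range(n_chrom):
        p = np.sort(rng.uniform(0.0, lengths[c], size=counts[c]))
        # enforce strict ordering under rare ties
        p += np.arange(counts[c]) * 1e-9
        positions.append(p)
    qtl_mask = np.zeros(n_loci, dtype=bool)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    # one guaranteed QTL per chromosome, remainder uniform over the rest
    guaranteed = np.array([rng.integers(offsets[c], offsets[c + 1]) for c in range(n_chrom)])
    qtl_mask[guaranteed] = True
    remaining = np.setdiff1d(np.arange(n_loci), guaranteed)
    extra = rng.choice(remaining, size=n_qtl - n_chrom, replace=False)
    qtl_mask[extra] = True
    return GeneticMap(lengths, positions, qtl_mask)


def load_genetic_map(path) -> GeneticMap:
    """Read a delimited map file with columns chrom, position_cM, is_qtl."""
    df = pd.read_csv(path)
    df = df.sort_values(["chrom", "position_cM"], kind="stable")
    positions, lengths, qtl = [], [], []
    for _, sub in df.groupby("chrom", sort=True):
        positions.append(sub["position_cM"].to_numpy(float))
        lengths.append(sub["position_cM"].max())
        qtl.append(sub["is_qtl"].to_numpy(int))
    return GeneticMap(np.array(lengths), positions, np.concatenate(qtl).astype(bool))


def haldane(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for map distance ``d_cM`` under Haldane's map."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

@dataclass
class FounderPopulation:
    """Inbred founder panel: haplotypes (n, 2, n_loci) in {0, 1}."""

    haplotypes: np.ndarray
    ids: list
    gmap: GeneticMap

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1)

    def qtl_dosages(self) -> np.ndarray:
        return self.dosages()[:, self.gmap.qtl_mask]

    def allele_freq(self) -> np.ndarray:
        return self.dosages().mean(axis=0) / 2.0

    def heterozygosity(self) -> np.ndarray:
        """Per-individual fraction of heterozygous loci."""
        return (self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean(axis=1)


def simulate_founders(n: int, gmap: GeneticMap, maf_min: float = 0.05,
                      rng: np.random.Generator | None = None,
                      max_rounds: int = 200) -> FounderPopulation:
    """Simulate ``n`` fully inbred founders with locus MAF >= ``maf_min``.

    Allele frequencies are drawn uniformly on [maf_min, 1 - maf_min]; loci
    whose realized minor allele frequency falls below the floor are redrawn,
    mirroring the marker-filtering rule applied to the real panel.
    """
    if n < 2:
        raise ConfigurationError("need at least two founders")
    if maf_min >= 0.5:
        raise ConfigurationError("maf_min must be < 0.5")
    rng = np.random.default_rng(rng)
    L = gmap.n_loci
    haps = np.zeros((n, L), dtype=np.int8)
    todo = np.arange(L)
    for _ in range(max_rounds):
        p = rng.uniform(maf_min, 1.0 - maf_min, size=todo.size)
        draw = (rng.random((n, todo.size)) < p).astype(np.int8)
        haps[:, todo] = draw
        freq = haps[:, todo].mean(axis=0)
        bad = np.minimum(freq, 1.0 - freq) < maf_min
        if not bad.any():
            break
        todo = todo[bad]
    else:  # pragma: no cover - tiny-n pathological case
        raise ConfigurationError("could not satisfy MAF floor; increase n or lower maf_min")
    full = np.repeat(haps[:, None, :], 2, axis=1)  # fully inbred
    ids = [f"FND{i:04d}" for i in range(n)]
    return FounderPopulation(full, ids, gmap)


def load_founders(path, gmap: GeneticMap) -> FounderPopulation:
    """Read a delimited genotype matrix (rows = lines, values 0/1/2).

    Dosage 1 is stored as a heterozygous locus.  The first column is the line
    identifier; remaining columns are loci in map order.
    """
    df = pd.read_csv(path, index_col=0)
    dos = df.to_numpy(dtype=np.int8)
    if dos.shape[1] != gmap.n_loci:
        raise ConfigurationError(f"genotype matrix has {dos.shape[1]} loci, map has {gmap.n_loci}")
    h0 = (dos >= 1).astype(np.int8)
    h1 = (dos == 2).astype(np.int8)
    haps = np.stack([h0, h1], axis=1)
    return FounderPopulation(haps, list(df.index.astype(str)), gmap)


# ---------------------------------------------------------------------------
# QTL effects
# ---------------------------------------------------------------------------

@dataclass
class QTLEffectSet:
    """Additive QTL effects: main (phi_G) and interaction matrices.

    ``phi_GL`` is q x J (per location), ``phi_GY`` q x K (per year),
    ``phi_GLY`` q x (J*K) stored column-major in location-year order.
    ``Sigma_J``/``Sigma_K`` hold the across-location / across-year covariances
    the interaction effects were drawn from (None for independent draws).
    """

    phi_G: np.ndarray
    phi_GL: np.ndarray | None = None
    phi_GY: np.ndarray | None = None
    phi_GLY: np.ndarray | None = None
    Sigma_J: np.ndarray | None = None
    Sigma_K: np.ndarray | None = None


def sample_qtl_effects(gmap: GeneticMap, sigma2_G_target: float,
                       founders: FounderPopulation,
                       rng: np.random.Generator | None = None) -> QTLEffectSet:
    """Draw i.i.d. normal QTL main effects and rescale them so the realized
    variance of breeding values among founders equals ``sigma2_G_target``."""
    if sigma2_G_target < 0:
        raise ConfigurationError("sigma2_G_target must be >= 0")
    rng = np.random.default_rng(rng)
    q = gmap.n_qtl
    phi = rng.standard_normal(q)
    if sigma2_G_target == 0:
        return QTLEffectSet(np.zeros(q))
    theta = founders.qtl_dosages().astype(float)
    bv = theta @ phi
    v = bv.var(ddof=0)
    if v <= 0:
        raise ConfigurationError("founders carry no genetic variance at the QTL")
    return QTLEffectSet(phi * np.sqrt(sigma2_G_target / v))


def breeding_values(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """True breeding values: dot product of QTL dosages and effects."""
    return np.asarray(theta, dtype=float) @ np.asarray(phi, dtype=float)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def gametes_batch(haps: np.ndarray, gmap: GeneticMap,
                  rng: np.random.Generator) -> np.ndarray:
    """Form one gamete per individual from haplotypes (N, 2, L) -> (N, L).

    Crossover counts are Poisson(length/100) per chromosome with uniform
    positions (no interference), which implies Haldane recombination
    fractions between locus pairs.
    """
    N = haps.shape[0]
    out = np.empty((N, haps.shape[2]), dtype=haps.dtype)
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_slice(c)
        pos = gmap.positions[c]
        length = gmap.chrom_lengths[c]
        ncx = rng.poisson(length / 100.0, size=N)
        maxc = int(ncx.max()) if N else 0
        parity = rng.integers(0, 2, size=N, dtype=np.int8).astype(bool)[:, None]
        parity = np.broadcast_to(parity, (N, len(pos))).copy()
        # accumulate crossover parity one uniform position per round;
        # rounds touch only gametes with that many crossovers left
        for c in range(1, maxc + 1):
            rows = np.flatnonzero(ncx >= c)
            u = rng.uniform(0.0, length, size=rows.size)
            parity[rows] ^= pos[None, :] > u[:, None]
        hc = haps[:, :, sl]
        out[:, sl] = np.where(~parity, hc[:, 0, :], hc[:, 1, :])
    return out


@dataclass
class Individual:
    """A single genotype with pedigree and generation bookkeeping."""

    id: str
    haplotypes: np.ndarray            # (2, L)
    gmap: GeneticMap
    generation: str = "F1"
    parents: tuple = (None, None)

    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)

    def qtl_dosage(self) -> np.ndarray:
        return self.dosage()[self.gmap.qtl_mask]


def cross(parent_a: Individual, parent_b: Individual,
          rng: np.random.Generator, id: str = "F1") -> Individual:
    """Biparental cross: one gamete from each parent."""
    if parent_a.haplotypes.shape != parent_b.haplotypes.shape:
        raise ConfigurationError("parents have mismatched locus counts")
    ga = gametes_batch(parent_a.haplotypes[None], parent_a.gmap, rng)[0]
    gb = gametes_batch(parent_b.haplotypes[None], parent_b.gmap, rng)[0]
    return Individual(id, np.stack([ga, gb]), parent_a.gmap, "F1",
                      (parent_a.id, parent_b.id))


def self_progeny(ind: Individual, n_offspring: int,
                 rng: np.random.Generator) -> list:
    """Self-pollinate: each offspring receives two independent gametes."""
    reps = np.repeat(ind.haplotypes[None], 2 * n_offspring, axis=0)
    g = gametes_batch(reps, ind.gmap, rng)
    out = []
    for i in range(n_offspring):
        haps = np.stack([g[2 * i], g[2 * i + 1]])
        out.append(Individual(f"{ind.id}.{i}", haps, ind.gmap, "self",
                              (ind.id, ind.id)))
    return out


def develop_line(f2: Individual, rng: np.random.Generator) -> Individual:
    """Advance an F2 (S0) plant to an F4:5 experimental line without selection.

    2-3 F3 progeny are sampled, one is advanced by selfing to F4; a single F4
    genotype represents the bulked F4:5 line thereafter.
    """
    k = int(rng.integers(2, 4))
    f3s = self_progeny(f2, k, rng)
    f3 = f3s[int(rng.integers(0, k))]
    f4 = self_progeny(f3, 1, rng)[0]
    f4.generation = "F4:5"
    f4.id = f2.id + ":L"
    f4.parents = f2.parents
    return f4


def develop_lines_batch(f2_haps: np.ndarray, gmap: GeneticMap,
                        rng: np.random.Generator) -> np.ndarray:
    """Vectorized F2 -> F4:5 development for a cohort (N, 2, L) -> (N, 2, L).

    Each F2 is selfed twice (F3 then F4); the sampled F3/F4 individual stands
    for the line (2-3 F3 progeny are drawn, one representative is kept, so a
    single selfing chain per line suffices distributionally).
    """
    f3 = np.stack([gametes_batch(f2_haps, gmap, rng),
                   gametes_batch(f2_haps, gmap, rng)], axis=1)
    f4 = np.stack([gametes_batch(f3, gmap, rng),
                   gametes_batch(f3, gmap, rng)], axis=1)
    return f4


# ---------------------------------------------------------------------------
# genomic relationship
# ---------------------------------------------------------------------------

def genomic_relationship(dosage: np.ndarray) -> np.ndarray:
    """Additive genomic relationship matrix (VanRaden centering).

    ``G = W W' / (2 sum p(1-p))`` with ``W`` the dosage matrix centered by
    twice the observed allele frequencies.  Monomorphic loci carry no
    information and are dropped; an all-monomorphic input is an error.
    """
    M = np.asarray(dosage, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ConfigurationError("need a 2-D dosage matrix with >= 2 lines")
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ConfigurationError("fewer than two polymorphic loci")
    W = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return W @ W.T / denom
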