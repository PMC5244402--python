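"""Synthetic haploid SSR datasets with controlled hierarchical structure.

The generator works at the allele-frequency level (a Balding–Nichols-style
compound Dirichlet hierarchy) rather than through a coalescent: the
downstream analyses only ever see frequencies and genotypes, and the F-model
gives direct control over F_ST-scale differentiation.

Per locus, a global ancestral frequency vector is drawn from a symmetric
Dirichlet; each region pool is drawn from Dirichlet(p_anc * (1-F)/F) with
F = ``F_region`` (variance of the compound around p_anc scales with F), and
each population likewise around its region pool with ``F_pop``.  Then, in
order:

1. isolation by distance — per-allele log frequencies are perturbed by a
   Gaussian field spatially correlated as exp(-d / ibd_range_km), with the
   field sd scaled up on rare alleles (new variants stay local), so genetic
   divergence grows smoothly with distance in every direction; colonisation
   events then act on an already spatially structured pool;
2. founder truncation — populations with ``founder_k`` keep only the first
   k alleles of a per-region colonisation order (Gumbel top-k with survival
   odds ~ frequency**founder_bias, so the rare tail is lost first and
   founder subsets of sister populations are nested — a single colonisation
   wave), then renormalise (the island founder effect);
3. migration admixture — population frequencies are mixed with the source
   region pools according to a directed region-to-region rate matrix.

Individuals are then drawn i.i.d. from their population frequencies, and
corruption is applied in the fixed order clone -> linkage -> missingness
(changing the order would change the nulls of the downstream tests).
Mating-type idiomorphs are Bernoulli(``mat_ratio``), with an optional
amplification-failure probability.  A single seeded generator stream governs
every draw, so identical configs give byte-identical outputs, and a
``TruthRecord`` keeps every latent quantity for oracle checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeDataset, MatTable, SitesTable
from .spatial import haversine_km


@dataclass
class PopulationConfig:
    name: str
    n_samples: int
    latitude: float
    longitude: float
    founder_k: Optional[int] = None   # cap on distinct founding alleles per locus


@dataclass
class RegionConfig:
    name: str
    populations: List[PopulationConfig]


@dataclass
class SimulationConfig:
    regions: List[RegionConfig]
    seed: int = 0
    n_loci: int = 8
    alleles_per_locus: Union[Tuple[int, int], Sequence[int]] = (16, 46)
    F_region: float = 0.05
    F_pop: float = 0.02
    migration: Dict[str, Dict[str, float]] = field(default_factory=dict)
    ibd_decay: float = 0.0            # sd of the spatial log-frequency field, [0, 1]
    clonality_rate: float = 0.0
    linkage_rho: float = 0.0
    missing_rate: float = 0.0
    mat_ratio: float = 0.5            # P(MAT1-1) among amplified samples
    mat_none_rate: float = 0.0        # P(amplification failure)
    ancestral_concentration: float = 1.0
    founder_bias: float = 2.0         # founder survival odds ~ freq**bias
    ibd_range_km: float = 1000.0      # correlation range of the spatial field

    def validate(self) -> None:
        if not self.regions or not any(r.populations for r in self.regions):
            raise ValueError("need at least one region with one population")
        names = [p.name for r in self.regions for p in r.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        for r in self.regions:
            for p in r.populations:
                if p.n_samples < 1:
                    raise ValueError(f"population {p.name}: n_samples must be >= 1")
        for prob, label in [(self.F_region, "F_region"), (self.F_pop, "F_pop"),
                            (self.ibd_decay, "ibd_decay"),
                            (self.clonality_rate, "clonality_rate"),
                            (self.linkage_rho, "linkage_rho"),
                            (self.missing_rate, "missing_rate"),
                            (self.mat_ratio, "mat_ratio"),
                            (self.mat_none_rate, "mat_none_rate")]:
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {prob}")
        region_names = {r.name for r in self.regions}
        incoming: Dict[str, float] = {}
        for src, dests in self.migration.items():
            if src not in region_names:
                raise ValueError(f"migration source {src!r} is not a region")
            for dst, rate in dests.items():
                if dst not in region_names:
                    raise ValueError(f"migration destination {dst!r} is not a region")
                if not 0.0 <= rate <= 1.0:
                    raise ValueError("migration rates must be in [0, 1]")
                incoming[dst] = incoming.get(dst, 0.0) + rate
        for dst, tot in incoming.items():
            if tot > 1.0:
                raise ValueError(f"total migration into {dst!r} exceeds 1")

    def inventory_sizes(self, rng: np.random.Generator) -> np.ndarray:
        a = self.alleles_per_locus
        if len(a) == 2 and self.n_loci != 2:
            lo, hi = int(a[0]), int(a[1])
            return rng.integers(lo, hi + 1, size=self.n_loci)
        if len(a) == self.n_loci:
            return np.array([int(v) for v in a])
        lo, hi = int(a[0]), int(a[1])
        return rng.integers(lo, hi + 1, size=self.n_loci)

    @property
    def populations(self) -> List[PopulationConfig]:
        return [p for r in self.regions for p in r.populations]

    @property
    def total_samples(self) -> int:
        return sum(p.n_samples for p in self.populations)


@dataclass
class TruthRecord:
    """Latent state of one simulation run, for oracle checks."""

    allele_labels: Dict[str, List[int]]                 # locus -> fragment lengths
    ancestral_freqs: Dict[str, List[float]]
    region_freqs: Dict[str, Dict[str, List[float]]]     # region -> locus -> freqs
    population_freqs: Dict[str, Dict[str, List[float]]] # final, post admixture/IBD
    founder_alleles: Dict[str, Dict[str, List[int]]]    # pop -> locus -> surviving labels
    clone_parent: Dict[str, Optional[str]]              # sample -> copied sample or None
    missing_mask: List[List[bool]]
    seed: int

    def n_clones(self) -> int:
        return sum(1 for v in self.clone_parent.values() if v is not None)

    def total_inventory(self) -> int:
        return sum(len(v) for v in self.allele_labels.values())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _compound_dirichlet(rng: np.random.Generator, base: np.ndarray, F: float) -> np.ndarray:
    """Balding–Nichols compound: Dirichlet(base * (1-F)/F); F=0 returns base."""
    if F <= 0:
        return base.copy()
    alpha = np.maximum(base, 1e-12) * (1.0 - F) / F
    return rng.dirichlet(alpha)


def simulate(config: SimulationConfig
             ) -> Tuple[GenotypeDataset, SitesTable, MatTable, TruthRecord]:
    """Generate one dataset under the hierarchical frequency model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = config.populations
    region_of = {p.name: r.name for r in config.regions for p in r.populations}
    loci = [f"Pcar{j + 1}" for j in range(config.n_loci)]
    sizes = config.inventory_sizes(rng)

    allele_labels = {loci[j]: [100 + 50 * j + 2 * i for i in range(sizes[j])]
                     for j in range(config.n_loci)}
    anc: Dict[str, np.ndarray] = {}
    reg_freqs: Dict[str, Dict[str, np.ndarray]] = {r.name: {} for r in config.regions}
    pop_freqs: Dict[str, Dict[str, np.ndarray]] = {p.name: {} for p in pops}
    founder: Dict[str, Dict[str, List[int]]] = {p.name: {} for p in pops}

    # isolation by distance: a spatially correlated Gaussian field perturbs
    # per-allele log frequencies, with correlation exp(-d / range) between
    # populations, so genetic divergence grows smoothly with distance in
    # every direction
    chol_ibd = None
    if config.ibd_decay > 0 and len(pops) > 1:
        lat = np.array([p.latitude for p in pops])
        lon = np.array([p.longitude for p in pops])
        d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        K = np.exp(-d / config.ibd_range_km)
        chol_ibd = np.linalg.cholesky(K + 1e-9 * np.eye(len(pops)))

    for j, locus in enumerate(loci):
        A = sizes[j]
        p_anc = rng.dirichlet(np.full(A, config.ancestral_concentration))
        anc[locus] = p_anc
        for r in config.regions:
            reg_freqs[r.name][locus] = _compound_dirichlet(rng, p_anc, config.F_region)
        base = {p.name: _compound_dirichlet(rng, reg_freqs[r.name][locus], config.F_pop)
                for r in config.regions for p in r.populations}
        # spatial autocorrelation, applied before founder events so that
        # colonisation truncates an already spatially structured pool
        if chol_ibd is not None:
            Z = chol_ibd @ rng.standard_normal((len(pops), A))
            # rare alleles carry most of the spatial signal (new variants
            # stay local), so the field sd scales inversely with frequency
            w = 1.0 / np.sqrt(p_anc + 0.02)
            w = w / w.mean()
            for i, p in enumerate(pops):
                f = base[p.name] * np.exp(config.ibd_decay * w * Z[i])
                base[p.name] = f / f.sum()
        for r in config.regions:
            incoming = [(src, rates[r.name])
                        for src, rates in config.migration.items()
                        if r.name in rates and rates[r.name] > 0]
            m_in = sum(rate for _, rate in incoming)
            # one colonisation order per region x locus: founder subsets of
            # sister populations are nested (a single colonisation wave),
            # alleles ranked by a frequency-biased draw from the region pool
            arrival = None
            if any(p.founder_k is not None for p in r.populations):
                # Gumbel top-k with survival odds ~ p^founder_bias: common
                # alleles almost surely survive, the rare tail is lost first
                pool = reg_freqs[r.name][locus]
                keys = (config.founder_bias * np.log(np.maximum(pool, 1e-300))
                        + rng.gumbel(size=A))
                arrival = np.argsort(-keys)
            for p in r.populations:
                f = base[p.name]
                if p.founder_k is not None:
                    k = min(p.founder_k, int(np.sum(f > 0)))
                    chosen = [i for i in arrival if f[i] > 0][:k]
                    mask = np.zeros(A, dtype=bool)
                    mask[chosen] = True
                    f = np.where(mask, f, 0.0)
                    f = f / f.sum()
                    founder[p.name][locus] = [allele_labels[locus][i]
                                              for i in sorted(chosen)]
                # migration admixture: destination pops receive source pools
                f = (1.0 - m_in) * f
                for src, rate in incoming:
                    f = f + rate * reg_freqs[src][locus]
                pop_freqs[p.name][locus] = f / f.sum()

    # draw individuals
    sample_ids: List[str] = []
    pop_of: Dict[str, str] = {}
    calls = np.empty((config.total_samples, config.n_loci), dtype=np.int64)
    clone_parent: Dict[str, Optional[str]] = {}
    row = 0
    for p in pops:
        start = row
        # frequency-rank maps for the linkage corruption
        rank_maps = []
        for locus in loci:
            order = np.argsort(-pop_freqs[p.name][locus], kind="stable")
            rank_of = np.empty_like(order)
            rank_of[order] = np.arange(order.size)
            rank_maps.append((rank_of, order))
        for i in range(p.n_samples):
            sid = f"{p.name}_{i + 1:03d}"
            sample_ids.append(sid)
            pop_of[sid] = p.name
            genotype = np.array([
                rng.choice(sizes[j], p=pop_freqs[p.name][loci[j]])
                for j in range(config.n_loci)], dtype=np.int64)
            clone_parent[sid] = None
            if i > 0 and config.clonality_rate > 0 and rng.random() < config.clonality_rate:
                src = int(rng.integers(start, row))
                genotype = calls[src].copy()
                clone_parent[sid] = sample_ids[src]
            if config.linkage_rho > 0:
                for j in range(1, config.n_loci):
                    if rng.random() < config.linkage_rho:
                        prev_rank = rank_maps[j - 1][0][genotype[j - 1]]
                        rank = min(int(prev_rank), sizes[j] - 1)
                        genotype[j] = rank_maps[j][1][rank]
            calls[row] = genotype
            row += 1

    # missingness, applied last
    mask = rng.random(calls.shape) < config.missing_rate
    labeled = np.empty_like(calls)
    for j, locus in enumerate(loci):
        labels = np.array(allele_labels[locus])
        labeled[:, j] = labels[calls[:, j]]
    labeled[mask] = MISSING

    data = GenotypeDataset(sample_ids, loci, labeled, pop_of, dict(region_of))
    sites = SitesTable(pd.DataFrame({
        "population": [p.name for p in pops],
        "region": [region_of[p.name] for p in pops],
        "latitude": [p.latitude for p in pops],
        "longitude": [p.longitude for p in pops],
    }))
    idio = []
    for sid in sample_ids:
        if rng.random() < config.mat_none_rate:
            idio.append("NONE")
        elif rng.random() < config.mat_ratio:
            idio.append("MAT1-1")
        else:
            idio.append("MAT1-2")
    mat = MatTable(pd.DataFrame({"sample_id": sample_ids, "idiomorph": idio}))

    truth = TruthRecord(
        allele_labels={l: list(map(int, v)) for l, v in allele_labels.items()},
        ancestral_freqs={l: list(map(float, anc[l])) for l in loci},
        region_freqs={r: {l: list(map(float, f)) for l, f in d.items()}
                      for r, d in reg_freqs.items()},
        population_freqs={p: {l: list(map(float, f)) for l, f in d.items()}
                          for p, d in pop_freqs.items()},
        founder_alleles=founder,
        clone_parent=clone_parent,
        missing_mask=mask.tolist(),
        seed=config.seed,
    )
    return data, sites, mat, truth


def paper_scale_config(seed: int = 0) -> SimulationConfig:
    """Default configuration mirroring the study's sampling design.

    Eleven populations in two regions — three Macaronesian island
    populations and eight Mediterranean mainland populations — with
    per-population sizes (25, 20, 20, 20, 8, 21, 17, 29, 25, 14, 21)
    totalling 220 haploid individuals (mean 20), eight hypervariable loci
    with allele inventories between 16 and 46 (220 alleles in total), 3%
    missing calls and balanced mating types with a 7% amplification-failure
    rate.  Island populations carry a founder bottleneck and receive
    asymmetric mainland->island migration; frequencies are spatially
    smoothed to produce isolation by distance.  Coordinates approximate the
    sampled localities and span roughly 3,000 km.
    """
    islands = RegionConfig("Macaronesia", [
        PopulationConfig("Tenerife", 25, 28.35, -16.55, founder_k=12),
        PopulationConfig("GranCanaria1", 20, 28.05, -15.58, founder_k=12),
        PopulationConfig("GranCanaria2", 20, 27.95, -15.57, founder_k=12),
    ])
    mainland = RegionConfig("Mainland", [
        PopulationConfig("Morocco", 20, 33.43, -5.10),
        PopulationConfig("Cadiz", 8, 36.50, -5.60),
        PopulationConfig("Marvao", 21, 39.40, -7.38),
        PopulationConfig("Covilha", 17, 40.28, -7.50),
        PopulationConfig("Famalicao", 29, 41.41, -8.52),
        PopulationConfig("Gredos", 25, 40.26, -5.14),
        PopulationConfig("Herbes", 14, 40.72, 0.02),
        PopulationConfig("Sicily", 21, 37.90, 14.00),
    ])
    return SimulationConfig(
        regions=[islands, mainland],
        seed=seed,
        n_loci=8,
        alleles_per_locus=(16, 22, 25, 26, 27, 28, 46, 30),  # total 220
        F_region=0.004,
        F_pop=0.004,
        migration={"Mainland": {"Macaronesia": 0.12}},
        ibd_decay=0.5,
        ibd_range_km=1000.0,
        clonality_rate=0.0,
        linkage_rho=0.0,
        missing_rate=0.03,
        mat_ratio=0.5,
        mat_none_rate=0.07,
        ancestral_concentration=0.8,
        founder_bias=4.0,
    )
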