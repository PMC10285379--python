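"""Forward-in-time simulation of livestock- and human-like populations.

The simulator generates the study populations used throughout the package:
a neutral historical phase (random mating at effective size ``Ne`` for 100
generations, which builds up linkage disequilibrium and a drifted allele
frequency spectrum from markers started at frequency 0.5), followed by a
recent phase of pedigreed generations under one of three designs:

* scenario 1 — livestock-like: ``Ne = 100`` historical, expansion to 1,000
  over the last five historical generations, then a paternal half-sib
  design (each sire mated to ``dams_per_sire`` dams, two offspring per
  dam);
* scenario 2 — human-like: ``Ne = 1,000`` historical, constant census,
  then monogamous full-sib pairs (two offspring per pair);
* scenario 3 — ``Ne = 100`` historical (as scenario 1) with the full-sib
  recent design of scenario 2.

Meiosis follows the Haldane model: crossover counts are Poisson with mean
1 per 100 cM, placed uniformly; symmetric allele-flip mutations occur at
2.8e-8 per locus per meiosis.  Phenotypes follow an additive model with
1,000 causal markers whose per-allele effects are scaled by
``[2p(1-p)]^alpha_true``; the genetic values are standardised to variance
``h2`` and residuals drawn with variance ``1 - h2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree, PedigreeRecord

__all__ = [
    "GenomeSpec",
    "ScenarioConfig",
    "PhenotypeSimConfig",
    "Population",
    "simulate_scenario",
    "simulate_phenotypes",
    "export_dataset",
]


@dataclass
class GenomeSpec:
    """Marker genome: 30 chromosomes x 300 markers on 100 cM by default."""

    n_chromosomes: int = 30
    chromosome_length_cM: float = 100.0
    markers_per_chromosome: int = 300
    mutation_rate: float = 2.8e-8
    initial_freq: float = 0.5

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.markers_per_chromosome

    def realize_positions(self, rng: np.random.Generator) -> list[np.ndarray]:
        """Draw sorted uniform marker positions (cM) per chromosome."""
        return [
            np.sort(rng.uniform(0.0, self.chromosome_length_cM,
                                self.markers_per_chromosome))
            for _ in range(self.n_chromosomes)
        ]


@dataclass
class ScenarioConfig:
    """Population design; defaults reproduce scenario 1 at full scale."""

    scenario: int = 1
    ne_historical: int = 100
    n_historical_generations: int = 100
    n_expansion_generations: int = 5      # growth phase ending the history
    expansion_target: int = 1000
    n_sires: int = 50                     # half-sib design (scenarios 1)
    dams_per_sire: int = 10
    offspring_per_dam: int = 2
    n_pairs: int = 500                    # full-sib design (scenarios 2-3)
    offspring_per_pair: int = 2
    n_recent_generations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.scenario == 2:
            # human-like: large constant historical census, no expansion
            self.ne_historical = max(self.ne_historical, 2 * self.n_pairs)
            self.n_expansion_generations = 0

    @property
    def mating_design(self) -> str:
        return "half_sib" if self.scenario == 1 else "full_sib"

    @property
    def n_founders(self) -> int:
        if self.scenario == 1:
            return self.n_sires * (1 + self.dams_per_sire)
        return 2 * self.n_pairs

    @property
    def offspring_per_generation(self) -> int:
        if self.scenario == 1:
            return self.n_sires * self.dams_per_sire * self.offspring_per_dam
        return self.n_pairs * self.offspring_per_pair


@dataclass
class PhenotypeSimConfig:
    n_causal: int = 1000
    h2: float = 0.5
    alpha_true: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie strictly between 0 and 1")


@dataclass
class Population:
    """Realized analysis population: founders plus the recent generations."""

    ids: list[str]
    sire: list[str]                      # UNKNOWN for founders
    dam: list[str]
    sex: np.ndarray                      # 1 male, 2 female
    generation: np.ndarray               # 0 founders, 1..n recent
    haplotypes: np.ndarray               # (n, 2, L) uint8
    positions: list[np.ndarray]          # per-chromosome marker cM
    genome: GenomeSpec
    config: ScenarioConfig
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.snp_ids:
            self.snp_ids = [
                f"chr{c + 1}_snp{m + 1}"
                for c in range(self.genome.n_chromosomes)
                for m in range(len(self.positions[c]))
            ]

    @property
    def n(self) -> int:
        return len(self.ids)

    def pedigree(self) -> Pedigree:
        recs = [
            PedigreeRecord(i, s, d, int(g))
            for i, s, d, g in zip(self.ids, self.sire, self.dam, self.generation)
        ]
        return Pedigree(recs)

    def ids_of_generations(self, generations) -> list[str]:
        gens = set(generations)
        return [i for i, g in zip(self.ids, self.generation) if int(g) in gens]

    def last_generations(self, k: int = 2) -> list[str]:
        top = int(self.generation.max())
        return self.ids_of_generations(range(top - k + 1, top + 1))

    def genotypes(self, ids=None) -> GenotypeMatrix:
        if ids is None:
            ids = self.ids
        pos = {ident: i for i, ident in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        counts = self.haplotypes[idx].sum(axis=1).astype(float)
        return GenotypeMatrix(counts, list(ids), list(self.snp_ids))


# ---------------------------------------------------------------------------
# meiosis


def _gametes(
    haps: np.ndarray,
    parent_idx: np.ndarray,
    positions: list[np.ndarray],
    length_cM: float,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete per entry of ``parent_idx`` (vectorised).

    ``haps`` is (n_parents, 2, L_total); returns (B, L_total) uint8.
    """
    B = parent_idx.size
    L_total = haps.shape[2]
    out = np.empty((B, L_total), dtype=np.uint8)
    offset = 0
    for pos in positions:
        L = pos.size
        n_x = rng.poisson(length_cM / 100.0, B)
        starts = rng.integers(0, 2, B)
        flips = np.zeros((B, L + 1), dtype=np.int64)
        total = int(n_x.sum())
        if total:
            gidx = np.repeat(np.arange(B), n_x)
            xpos = rng.uniform(0.0, length_cM, total)
            ins = np.searchsorted(pos, xpos)
            np.add.at(flips, (gidx, ins), 1)
        which = (starts[:, None] + np.cumsum(flips[:, :L], axis=1)) % 2
        h0 = haps[parent_idx, 0, offset:offset + L]
        h1 = haps[parent_idx, 1, offset:offset + L]
        out[:, offset:offset + L] = np.where(which == 0, h0, h1)
        offset += L
    # symmetric allele-flip mutation, ~Binomial(B*L, mu) events genome-wide
    n_mut = rng.binomial(B * L_total, mutation_rate)
    if n_mut:
        gi = rng.integers(0, B, n_mut)
        li = rng.integers(0, L_total, n_mut)
        out[gi, li] ^= 1
    return out


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly ordered sexes with an exactly balanced split (1 M, 2 F)."""
    sex = np.full(n, 2, dtype=np.int8)
    sex[: n // 2] = 1
    rng.shuffle(sex)
    return sex


def _random_union_offspring(
    haps, sex, n_offspring, genome, positions, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Random union of gametes (two-sex Wright-Fisher) for the historical
    phase: every offspring draws its sire and dam independently, so the
    effective size tracks the census size."""
    males = np.flatnonzero(sex == 1)
    females = np.flatnonzero(sex == 2)
    if males.size == 0 or females.size == 0:
        raise ValueError("historical generation lost one sex entirely")
    sire_idx = rng.choice(males, n_offspring)
    dam_idx = rng.choice(females, n_offspring)
    pat = _gametes(haps, sire_idx, positions, genome.chromosome_length_cM,
                   genome.mutation_rate, rng)
    mat = _gametes(haps, dam_idx, positions, genome.chromosome_length_cM,
                   genome.mutation_rate, rng)
    return np.stack([pat, mat], axis=1), _balanced_sexes(n_offspring, rng)


def simulate_historical(
    cfg: ScenarioConfig,
    genome: GenomeSpec,
    rng: np.random.Generator,
    positions: list[np.ndarray] | None = None,
    n_generations: int | None = None,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Run the unpedigreed historical phase; returns (haps, sex, positions)."""
    if positions is None:
        positions = genome.realize_positions(rng)
    L = sum(p.size for p in positions)
    ne = cfg.ne_historical
    haps = (rng.random((ne, 2, L)) < genome.initial_freq).astype(np.uint8)
    sex = _balanced_sexes(ne, rng)

    total = cfg.n_historical_generations if n_generations is None else n_generations
    n_exp = min(cfg.n_expansion_generations, total) if n_generations is None else 0
    n_const = total - n_exp
    for _ in range(n_const):
        haps, sex = _random_union_offspring(haps, sex, ne, genome, positions, rng)
    if n_exp:
        sizes = np.linspace(ne, cfg.expansion_target, n_exp + 1)[1:]
        for size in sizes:
            haps, sex = _random_union_offspring(
                haps, sex, int(round(size)), genome, positions, rng
            )
    return haps, sex, positions


def simulate_scenario(
    cfg: ScenarioConfig,
    genome: GenomeSpec | None = None,
    seed: int | None = None,
) -> Population:
    """Simulate one full scenario and return the analysis population."""
    genome = genome or GenomeSpec()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    haps_hist, sex_hist, positions = simulate_historical(cfg, genome, rng)
    n_hist = haps_hist.shape[0]

    # --- select founders from the last historical generation
    males = np.flatnonzero(sex_hist == 1)
    females = np.flatnonzero(sex_hist == 2)
    if cfg.scenario == 1:
        n_m, n_f = cfg.n_sires, cfg.n_sires * cfg.dams_per_sire
    else:
        n_m = n_f = cfg.n_pairs
    if males.size < n_m or females.size < n_f:
        raise ValueError(
            f"design needs {n_m} males and {n_f} females but the last "
            f"historical generation (n={n_hist}) has {males.size}/{females.size}"
        )
    chosen = np.concatenate([rng.choice(males, n_m, replace=False),
                             rng.choice(females, n_f, replace=False)])
    haps = haps_hist[chosen]
    sex = np.concatenate([np.ones(n_m, np.int8), np.full(n_f, 2, np.int8)])

    ids = [str(i + 1) for i in range(cfg.n_founders)]
    sire_l = [UNKNOWN] * cfg.n_founders
    dam_l = [UNKNOWN] * cfg.n_founders
    gen_l = [0] * cfg.n_founders
    all_haps = [haps]
    all_sex = [sex.copy()]
    next_id = cfg.n_founders + 1
    par_ids = np.array(ids)

    for g in range(1, cfg.n_recent_generations + 1):
        males = np.flatnonzero(sex == 1)
        females = np.flatnonzero(sex == 2)
        if cfg.scenario == 1:
            if males.size < cfg.n_sires or females.size < cfg.n_sires * cfg.dams_per_sire:
                raise ValueError(
                    f"generation {g}: not enough parents for the half-sib design"
                )
            sires = rng.choice(males, cfg.n_sires, replace=False)
            dams = rng.choice(females, cfg.n_sires * cfg.dams_per_sire, replace=False)
            dams = rng.permutation(dams)
            sire_per_off = np.repeat(
                np.repeat(sires, cfg.dams_per_sire), cfg.offspring_per_dam
            )
            dam_per_off = np.repeat(dams, cfg.offspring_per_dam)
        else:
            if males.size < cfg.n_pairs or females.size < cfg.n_pairs:
                raise ValueError(
                    f"generation {g}: not enough parents for the full-sib design"
                )
            pm = rng.choice(males, cfg.n_pairs, replace=False)
            pf = rng.choice(females, cfg.n_pairs, replace=False)
            sire_per_off = np.repeat(pm, cfg.offspring_per_pair)
            dam_per_off = np.repeat(pf, cfg.offspring_per_pair)

        n_off = sire_per_off.size
        pat = _gametes(haps, sire_per_off, positions,
                       genome.chromosome_length_cM, genome.mutation_rate, rng)
        mat = _gametes(haps, dam_per_off, positions,
                       genome.chromosome_length_cM, genome.mutation_rate, rng)
        off_haps = np.stack([pat, mat], axis=1)
        off_sex = _balanced_sexes(n_off, rng)

        off_ids = [str(next_id + i) for i in range(n_off)]
        next_id += n_off
        ids.extend(off_ids)
        sire_l.extend(par_ids[sire_per_off].tolist())
        dam_l.extend(par_ids[dam_per_off].tolist())
        gen_l.extend([g] * n_off)
        all_haps.append(off_haps)
        all_sex.append(off_sex.copy())

        haps, sex, par_ids = off_haps, off_sex, np.array(off_ids)

    return Population(
        ids=ids,
        sire=sire_l,
        dam=dam_l,
        sex=np.concatenate(all_sex),
        generation=np.array(gen_l),
        haplotypes=np.concatenate(all_haps, axis=0),
        positions=positions,
        genome=genome,
        config=cfg,
    )


def simulate_phenotypes(
    pop: Population,
    cfg: PhenotypeSimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Additive phenotypes for every individual in the population.

    Causal markers are drawn from the marker panel; raw effects are
    standard normal and scaled by ``[2p(1-p)]^alpha_true`` with ``p`` the
    frequency among the phenotyped individuals.  Monomorphic draws are
    resampled.  Genetic values are standardised to variance ``h2`` and
    residuals drawn from N(0, 1 - h2).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    counts = pop.haplotypes.sum(axis=1).astype(float)
    p_all = counts.mean(axis=0) / 2.0
    poly = np.flatnonzero((p_all > 0.0) & (p_all < 1.0))
    if poly.size < cfg.n_causal:
        raise ValueError(
            f"only {poly.size} polymorphic markers; cannot draw {cfg.n_causal} causal"
        )
    causal = rng.choice(poly, cfg.n_causal, replace=False)
    u = rng.standard_normal(cfg.n_causal)
    pk = p_all[causal]
    gamma = u * (2.0 * pk * (1.0 - pk)) ** cfg.alpha_true
    g = counts[:, causal] @ gamma
    g = g - g.mean()
    sd = g.std()
    if sd <= 0:
        raise ValueError("degenerate genetic values (zero variance)")
    g = g * (np.sqrt(cfg.h2) / sd)
    e = rng.normal(0.0, np.sqrt(1.0 - cfg.h2), pop.n)
    y = g + e
    out = pd.DataFrame({
        "id": pop.ids,
        "trait": y,
        "genetic_value": g,
    })
    # per-locus architecture, for inspection of the effect-size/MAF relation
    out.attrs["causal_index"] = causal
    out.attrs["gamma"] = gamma
    out.attrs["maf"] = np.minimum(pk, 1.0 - pk)
    return out


def export_dataset(
    pop: Population,
    phenotypes: pd.DataFrame,
    outdir: str | Path,
    genotyped_generations: int = 2,
    exclude_causal: bool = False,
) -> dict:
    """Write pedigree CSV, phenotype TSV, PLINK .raw/.bed and a manifest.

    With ``exclude_causal=True`` the causal markers recorded by
    :func:`simulate_phenotypes` are removed from the exported genotype
    panel (by default they stay in, as markers).
    """
    from . import plinkio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ped_path = outdir / "pedigree.csv"
    with open(ped_path, "w") as fh:
        fh.write("id,sire,dam,generation\n")
        for i, s, d, g in zip(pop.ids, pop.sire, pop.dam, pop.generation):
            fh.write(f"{i},{s},{d},{g}\n")

    phe_path = outdir / "phenotypes.tsv"
    phenotypes[["id", "trait"]].to_csv(phe_path, sep="\t", index=False)

    geno_ids = pop.last_generations(genotyped_generations)
    gm = pop.genotypes(geno_ids)
    chrom = np.repeat(np.arange(1, pop.genome.n_chromosomes + 1),
                      [p.size for p in pop.positions])
    cm = np.concatenate(pop.positions)
    if exclude_causal:
        causal = np.asarray(phenotypes.attrs.get("causal_index", []), int)
        if causal.size == 0:
            raise ValueError("exclude_causal requires phenotypes from "
                             "simulate_phenotypes (no causal index found)")
        keep = np.setdiff1d(np.arange(gm.n_snps), causal)
        gm = GenotypeMatrix(gm.counts[:, keep], gm.ids,
                            [gm.snp_ids[k] for k in keep])
        chrom, cm = chrom[keep], cm[keep]
    raw_path = outdir / "genotypes.raw"
    plinkio.write_raw(gm, raw_path)
    bed_prefix = outdir / "genotypes"
    plinkio.write_bed(gm, bed_prefix, chromosomes=chrom, cm_positions=cm)

    manifest = {
        "scenario": asdict(pop.config),
        "genome": asdict(pop.genome),
        "n_individuals": pop.n,
        "n_genotyped": len(geno_ids),
        "n_markers": gm.n_snps,
        "causal_excluded": bool(exclude_causal),
        "files": {
            "pedigree": ped_path.name,
            "phenotypes": phe_path.name,
            "raw": raw_path.name,
            "bed": bed_prefix.name + ".bed",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
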