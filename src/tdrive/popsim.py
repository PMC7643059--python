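"""Seeded individual-based simulator of a closed house-mouse barn population
segregating the t haplotype.

Generates litter, pedigree and per-generation count tables with the
statistical structure the downstream analyses assume: multiply-sired
litters, paternity skew against +/t males in contested litters (share c),
drive transmission d within a +/t sire's share, and in-utero loss of t/t
conceptions (which thins realised litter sizes rather than resampling them).

Generations are discrete and non-overlapping; every adult breeds in exactly
one generation.  Sexes are assigned 50:50 at birth.  The adult population is
held at a carrying capacity by sampling the next generation's breeders
uniformly from the viable pups, sex by sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import poisson

from .drive import WW, WT

__all__ = [
    "SimConfig",
    "SimResult",
    "truncated_poisson_litter_dist",
    "simulate",
    "score_genetic_polyandry",
]

LITTER_COLUMNS = [
    "litter_id",
    "mother_id",
    "mother_genotype",
    "cohort",
    "pup_id",
    "pup_genotype",
    "sire_id",
]

PEDIGREE_COLUMNS = ["id", "dam", "sire", "sex", "genotype", "cohort"]


class ConfigError(ValueError):
    pass


def truncated_poisson_litter_dist(
    mean: float = 3.1, kmin: int = 1, kmax: int = 8
) -> dict[int, float]:
    """Poisson litter-size distribution truncated to {kmin..kmax} with the
    requested mean, the default matching the study population's average of
    roughly 3.1 pups per litter."""
    ks = np.arange(kmin, kmax + 1)

    def trunc_mean(lam: float) -> float:
        w = poisson.pmf(ks, lam)
        w = w / w.sum()
        return float((ks * w).sum())

    if not kmin < mean < kmax:
        raise ValueError(f"mean must lie strictly between {kmin} and {kmax}")
    lam = brentq(lambda x: trunc_mean(x) - mean, 1e-6, 4.0 * kmax)
    w = poisson.pmf(ks, lam)
    w = w / w.sum()
    return {int(k): float(p) for k, p in zip(ks, w)}


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults mirror the study system: a barn colony founded by 12 animals of
    which 4 carried t, drive strength d = 0.9, +/t competitiveness
    c = 0.113, and a constant behavioural polyandry rate P.  Each female has
    one to several reproductive events per generation (``litters_per_female``,
    default a truncated Poisson with mean 3 — roughly three litters per
    breeding female, as in the study), with mates drawn anew per event.
    ``n_adults`` caps the breeding population per generation (the barn's
    carrying capacity); ``n_litters``, when set, stops the run once that
    many litters have been recorded.
    """

    n_founders: int = 12
    n_t_founders: int = 4
    n_generations: int = 10
    n_litters: int | None = None
    n_adults: int | None = 200
    litter_size_dist: Mapping[int, float] | None = None
    litters_per_female: Mapping[int, float] | None = None
    P: float | Sequence[float] = 0.609
    d: float = 0.9
    c: float = 0.113
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ConfigError(f"need at least 2 founders, got {self.n_founders}")
        if not 0 <= self.n_t_founders <= self.n_founders:
            raise ConfigError("n_t_founders must lie in [0, n_founders]")
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        if self.n_adults is not None and self.n_adults < 2:
            raise ConfigError("n_adults must be >= 2 when set")
        for name in ("d", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for p in self._P_schedule(self.n_generations):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"P values must lie in [0, 1], got {p}")
        for name in ("litter_size_dist", "litters_per_female"):
            dist = getattr(self, name)
            if dist is not None:
                total = sum(dist.values())
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(f"{name} must sum to 1, got {total}")
                if any(k < 1 for k in dist):
                    raise ConfigError(f"{name} counts must be >= 1")

    def _P_schedule(self, n: int) -> list[float]:
        if isinstance(self.P, (int, float)):
            return [float(self.P)] * n
        seq = [float(p) for p in self.P]
        if not seq:
            raise ConfigError("P sequence must be nonempty")
        # extend with the last value if the run outlives the schedule
        return (seq + [seq[-1]] * n)[:n]


@dataclass
class SimResult:
    """Simulator output tables.

    ``litters`` has one row per viable pup; ``matings`` records every mate a
    female took for each recorded litter (including mates that achieved no
    paternity — information real paternity data lack); ``gen_counts`` gives
    per-generation adult and viable-newborn genotype counts.
    """

    litters: pd.DataFrame
    pedigree: pd.DataFrame
    gen_counts: pd.DataFrame
    matings: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def _draw_litter_size(rng: np.random.Generator, sizes: np.ndarray, probs: np.ndarray) -> int:
    return int(rng.choice(sizes, p=probs))


def simulate(config: SimConfig) -> SimResult:
    """Run the individual-based simulation; byte-identical output under a
    fixed (seed, config)."""
    rng = np.random.default_rng(config.seed)
    dist = config.litter_size_dist or truncated_poisson_litter_dist()
    sizes = np.array(sorted(dist), dtype=int)
    probs = np.array([dist[int(k)] for k in sizes], dtype=float)
    probs = probs / probs.sum()
    ldist = config.litters_per_female or truncated_poisson_litter_dist(mean=3.0)
    lcounts = np.array(sorted(ldist), dtype=int)
    lprobs = np.array([ldist[int(k)] for k in lcounts], dtype=float)
    lprobs = lprobs / lprobs.sum()
    P_sched = config._P_schedule(config.n_generations)

    next_id = 0

    def new_id() -> str:
        nonlocal next_id
        next_id += 1
        return f"I{next_id:06d}"

    # founders: genotypes assigned to random individuals, sexes balanced
    genotypes = np.array([WT] * config.n_t_founders + [WW] * (config.n_founders - config.n_t_founders))
    genotypes = genotypes[rng.permutation(config.n_founders)]
    sexes = np.array(["F", "M"] * ((config.n_founders + 1) // 2))[: config.n_founders]
    pedigree_rows: list[dict] = []
    females: list[tuple[str, str]] = []
    males: list[tuple[str, str]] = []
    for g, s in zip(genotypes, sexes):
        iid = new_id()
        pedigree_rows.append({"id": iid, "dam": "", "sire": "", "sex": s, "genotype": g, "cohort": 0})
        (females if s == "F" else males).append((iid, g))

    litter_rows: list[dict] = []
    mating_rows: list[dict] = []
    count_rows: list[dict] = []
    n_litters_done = 0
    litter_counter = 0

    for gen in range(config.n_generations):
        if not females or not males:
            break
        P = P_sched[gen]
        cohort = gen + 1
        male_ids = [m[0] for m in males]
        male_geno = {i: g for i, g in males}
        pups_f: list[tuple[str, str]] = []
        pups_m: list[tuple[str, str]] = []
        n_conceived = 0
        n_tt_lost = 0
        newborn_counts = {WW: 0, WT: 0}

        for mother_id, mother_geno in females:
            # each female has one to several reproductive events
            # (litters), with mates drawn anew for every event
            n_events = int(rng.choice(lcounts, p=lprobs))
            for _event in range(n_events):
                two = rng.random() < P and len(male_ids) >= 2
                if two:
                    idx = rng.choice(len(male_ids), size=2, replace=False)
                    mates = [male_ids[idx[0]], male_ids[idx[1]]]
                else:
                    mates = [male_ids[int(rng.integers(len(male_ids)))]]
                mate_genos = [male_geno[m] for m in mates]
                # per-pup probability of taking mate 0
                if len(mates) == 1:
                    p_first = 1.0
                elif mate_genos[0] == mate_genos[1]:
                    p_first = 0.5
                else:
                    p_first = config.c if mate_genos[0] == WT else 1.0 - config.c

                k_pre = _draw_litter_size(rng, sizes, probs)
                n_conceived += k_pre
                pups: list[tuple[str, str]] = []  # (genotype, sire_id)
                for _ in range(k_pre):
                    j = 0 if rng.random() < p_first else 1
                    sire_id, sire_geno = mates[j], mate_genos[j]
                    pat_t = sire_geno == WT and rng.random() < config.d
                    mat_t = mother_geno == WT and rng.random() < 0.5
                    if pat_t and mat_t:
                        n_tt_lost += 1  # t/t conceptus dies in utero
                        continue
                    pups.append((WT if (pat_t or mat_t) else WW, sire_id))
                if not pups:
                    continue  # whole litter lost before birth: never observed

                litter_counter += 1
                litter_id = f"L{litter_counter:05d}"
                mating_rows.append(
                    {
                        "litter_id": litter_id,
                        "mother_id": mother_id,
                        "cohort": cohort,
                        "n_mates": len(mates),
                        "mate1_id": mates[0],
                        "mate1_genotype": mate_genos[0],
                        "mate2_id": mates[1] if len(mates) == 2 else "",
                        "mate2_genotype": mate_genos[1] if len(mates) == 2 else "",
                    }
                )
                for geno, sire_id in pups:
                    pup_id = new_id()
                    sex = "F" if rng.random() < 0.5 else "M"
                    newborn_counts[geno] += 1
                    litter_rows.append(
                        {
                            "litter_id": litter_id,
                            "mother_id": mother_id,
                            "mother_genotype": mother_geno,
                            "cohort": cohort,
                            "pup_id": pup_id,
                            "pup_genotype": geno,
                            "sire_id": sire_id,
                        }
                    )
                    pedigree_rows.append(
                        {
                            "id": pup_id,
                            "dam": mother_id,
                            "sire": sire_id,
                            "sex": sex,
                            "genotype": geno,
                            "cohort": cohort,
                        }
                    )
                    (pups_f if sex == "F" else pups_m).append((pup_id, geno))
                n_litters_done += 1

        count_rows.append(
            {
                "cohort": cohort,
                "P": P,
                "adult_females": len(females),
                "adult_males": len(males),
                "adult_ww": sum(1 for _, g in females + males if g == WW),
                "adult_wt": sum(1 for _, g in females + males if g == WT),
                "female_wt": sum(1 for _, g in females if g == WT),
                "male_wt": sum(1 for _, g in males if g == WT),
                "newborn_ww": newborn_counts[WW],
                "newborn_wt": newborn_counts[WT],
                "conceived": n_conceived,
                "tt_lost": n_tt_lost,
            }
        )

        # recruit next generation's breeders, sex by sex, up to capacity
        if config.n_adults is not None:
            cap_f = config.n_adults // 2
            cap_m = config.n_adults - cap_f
            if len(pups_f) > cap_f:
                keep = rng.choice(len(pups_f), size=cap_f, replace=False)
                pups_f = [pups_f[i] for i in sorted(keep)]
            if len(pups_m) > cap_m:
                keep = rng.choice(len(pups_m), size=cap_m, replace=False)
                pups_m = [pups_m[i] for i in sorted(keep)]
        females, males = pups_f, pups_m

        if config.n_litters is not None and n_litters_done >= config.n_litters:
            break

    litters = pd.DataFrame(litter_rows, columns=LITTER_COLUMNS)
    pedigree = pd.DataFrame(pedigree_rows, columns=PEDIGREE_COLUMNS)
    gen_counts = pd.DataFrame(count_rows)
    matings = pd.DataFrame(
        mating_rows,
        columns=[
            "litter_id",
            "mother_id",
            "cohort",
            "n_mates",
            "mate1_id",
            "mate1_genotype",
            "mate2_id",
            "mate2_genotype",
        ],
    )
    return SimResult(litters=litters, pedigree=pedigree, gen_counts=gen_counts, matings=matings, config=config)


def score_genetic_polyandry(litters: pd.DataFrame) -> tuple[int, int]:
    """Count litters eligible for polyandry scoring and those with more than
    one genetic sire.

    Only litters of realised size >= 2 are eligible: a singleton cannot
    reveal multiple sires.  Returns (n_eligible, n_multisire).
    """
    if litters.empty:
        return 0, 0
    by_litter = litters.groupby("litter_id").agg(
        size=("pup_id", "size"), n_sires=("sire_id", "nunique")
    )
    eligible = by_litter[by_litter["size"] >= 2]
    return int(len(eligible)), int((eligible["n_sires"] >= 2).sum())
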