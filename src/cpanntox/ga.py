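"""Genetic-algorithm model optimization, acceptance rules and stability check.

A chromosome encodes a descriptor-selection mask together with the two
learning-rate genes (v_max, v_min).  Each chromosome is scored by training a
CPANN on the training set with the masked descriptors and evaluating one of
the optimization criteria (OC1-OC3, see :mod:`cpanntox.metrics`) on the
first test set (OC3 also uses the training set).  Selection is rank-based
from the top ``n_crossover_parents``, crossover is uniform on the mask with
an arithmetic blend of the rate genes, mutation is per-bit flip plus
clipped Gaussian perturbation of the genes, and one elite chromosome is
carried over unchanged (so the best criterion value never decreases).

Model acceptance applies two rules to the search history:

* rule 1 — a model is a candidate if sensitivity and specificity on TR, TE1
  and TE2 are all >= 0.7 and all three MCC are >= 0.5 (inclusive);
* rule 2 — if any of the three best-of-generation slots averages
  sensitivity and specificity >= 0.7 on all three sets over the last 20
  generations, all three best chromosomes of the final generation are
  selected as well.

Candidates are then retrained ``n_retrains`` times under different random
object orders (and, in balanced-subsample mode, fresh subsample draws); a
model is finally accepted when its mean sensitivity and mean specificity
stay >= 0.7 on all three sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics
from .cpann import CpannModel, TrainConfig, train_cpann, predict
from .dataprep import DescriptorDataset, zscore_fit
from .som import LearningSchedule

__all__ = [
    "Chromosome",
    "GAConfig",
    "EvaluatedChromosome",
    "GAHistory",
    "AcceptanceReport",
    "run_ga",
    "evaluate_chromosome",
    "accept_models",
    "stability_check",
]

SENS_SPEC_THRESHOLD = 0.7
MCC_THRESHOLD = 0.5
BEST3_WINDOW = 20


@dataclass(frozen=True)
class Chromosome:
    """Descriptor mask plus learning-rate genes."""

    mask: tuple[bool, ...]
    v_max_gene: float
    v_min_gene: float

    def __post_init__(self) -> None:
        if not any(self.mask):
            raise ValueError("chromosome must select at least one descriptor")
        if not 0.0 < self.v_max_gene <= 1.0:
            raise ValueError("v_max_gene must be in (0, 1]")
        if not 0.0 <= self.v_min_gene <= self.v_max_gene:
            raise ValueError("need 0 <= v_min_gene <= v_max_gene")

    @property
    def n_selected(self) -> int:
        return int(sum(self.mask))

    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.mask))


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 12
    n_generations: int = 10
    n_crossover_parents: int = 4
    mutation_rate: float = 0.05
    gene_sigma: float = 0.05
    criterion: str = "OC2"
    p: float = 0.0
    grid_shape: tuple[int, int] = (6, 6)
    epochs: int = 20
    mode: str = "full_epoch"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.criterion not in metrics.CRITERIA:
            raise ValueError(f"criterion must be one of {metrics.CRITERIA}")
        if not 2 <= self.n_crossover_parents <= self.population_size:
            raise ValueError("need 2 <= n_crossover_parents <= population_size")


@dataclass
class EvaluatedChromosome:
    """A chromosome with its trained model and per-set statistics."""

    chromosome: Chromosome
    criterion_value: float
    stats: dict[str, dict[str, float]]  # set name -> {sens, spec, mcc}
    model: CpannModel
    generation: int


@dataclass
class GAHistory:
    """Per-generation record of the whole search."""

    generations: list[list[EvaluatedChromosome]] = field(default_factory=list)

    @property
    def n_generations(self) -> int:
        return len(self.generations)

    def best(self) -> EvaluatedChromosome:
        return max(
            (e for gen in self.generations for e in gen),
            key=lambda e: e.criterion_value,
        )

    def best_per_generation(self, k: int = 1) -> list[list[EvaluatedChromosome]]:
        """Top-``k`` chromosomes of every generation, best first."""
        return [
            sorted(gen, key=lambda e: -e.criterion_value)[:k]
            for gen in self.generations
        ]

    def to_log(self) -> str:
        """Tab-separated audit log: generation, best criterion, best-3 stats."""
        lines = ["generation\tbest_criterion\t" + "\t".join(
            f"b{r}_{s}_{m}"
            for r in (1, 2, 3) for s in ("tr", "te1", "te2") for m in ("sens", "spec")
        )]
        for g, top3 in enumerate(self.best_per_generation(3), start=1):
            cells = [str(g), f"{top3[0].criterion_value:.6f}"]
            for r in range(3):
                if r < len(top3):
                    st = top3[r].stats
                    for s in ("TR", "TE1", "TE2"):
                        if s in st:
                            cells += [f"{st[s]['sens']:.4f}", f"{st[s]['spec']:.4f}"]
                        else:
                            cells += ["NA", "NA"]
                else:
                    cells += ["NA"] * 6
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


@dataclass
class AcceptanceReport:
    """Outcome of the retrain-stability check for one candidate model."""

    chromosome: Chromosome
    n_retrains: int
    mean: dict[str, dict[str, float]]
    sd: dict[str, dict[str, float]]
    accepted: bool


def _set_stats(model: CpannModel, part: DescriptorDataset) -> dict[str, float]:
    _, classes, _ = predict(model, part.X, descriptor_names=part.descriptor_names)
    c = metrics.confusion_counts(part.y, classes)
    return {
        "sens": metrics.sensitivity(c),
        "spec": metrics.specificity(c),
        "mcc": metrics.mcc(c),
    }


def evaluate_chromosome(
    chrom: Chromosome,
    dataset: DescriptorDataset,
    config: GAConfig,
    train_seed: int,
    generation: int = 0,
) -> EvaluatedChromosome:
    """Train a CPANN for one chromosome and score it.

    Normalization is fit on the training-set rows of the selected
    descriptors; TR, TE1 and (when present) TE2 statistics are computed on
    the trained model.
    """
    names = [dataset.descriptor_names[j] for j in chrom.selected_indices()]
    sub = dataset.select_descriptors(names)
    tr = sub.members("TR")
    if len(np.unique(tr.y)) < 2:
        raise ValueError("training set must contain both classes")
    norm = zscore_fit(tr.X, names)
    Xtr = (tr.X - norm.mean) / norm.sd
    schedule = LearningSchedule(
        v_max=chrom.v_max_gene, v_min=chrom.v_min_gene, epochs=config.epochs
    )
    tc = TrainConfig(
        grid_shape=config.grid_shape, schedule=schedule, mode=config.mode,
        seed=train_seed,
    )
    model = train_cpann(
        Xtr, tr.y, tc, descriptor_names=names,
        norm_mean=norm.mean, norm_sd=norm.sd,
    )
    stats = {"TR": _set_stats(model, tr)}
    for part in ("TE1", "TE2"):
        sel = sub.members(part)
        if sel.n_compounds:
            stats[part] = _set_stats(model, sel)
    if "TE1" not in stats:
        raise ValueError("dataset has no TE1 compounds")
    f = metrics.descriptor_penalty(config.p, chrom.n_selected, len(dataset.descriptor_names))
    value = metrics.optimization_criterion(
        config.criterion, f,
        sens_te1=stats["TE1"]["sens"], spec_te1=stats["TE1"]["spec"],
        mcc_te1=stats["TE1"]["mcc"], mcc_train=stats["TR"]["mcc"],
    )
    return EvaluatedChromosome(chrom, value, stats, model, generation)


def _random_chromosome(n_desc: int, rng: np.random.Generator) -> Chromosome:
    mask = rng.random(n_desc) < 0.5
    if not mask.any():
        mask[int(rng.integers(n_desc))] = True
    v_max = float(rng.uniform(0.1, 0.9))
    v_min = float(rng.uniform(0.0, v_max))
    return Chromosome(tuple(bool(b) for b in mask), v_max, v_min)


def _crossover(p1: Chromosome, p2: Chromosome, rng: np.random.Generator) -> Chromosome:
    pick = rng.random(len(p1.mask)) < 0.5
    mask = np.where(pick, np.asarray(p1.mask), np.asarray(p2.mask))
    u = float(rng.random())
    v_max = u * p1.v_max_gene + (1 - u) * p2.v_max_gene
    v_min = u * p1.v_min_gene + (1 - u) * p2.v_min_gene
    if not mask.any():
        mask[int(rng.integers(len(mask)))] = True
    return Chromosome(tuple(bool(b) for b in mask),
                      min(max(v_max, 1e-6), 1.0), min(v_min, v_max))


def _mutate(chrom: Chromosome, config: GAConfig, rng: np.random.Generator) -> Chromosome:
    mask = np.asarray(chrom.mask).copy()
    flips = rng.random(len(mask)) < config.mutation_rate
    mask[flips] = ~mask[flips]
    if not mask.any():  # repair: keep at least one descriptor
        mask[int(rng.integers(len(mask)))] = True
    v_max = chrom.v_max_gene + float(rng.normal(0, config.gene_sigma))
    v_min = chrom.v_min_gene + float(rng.normal(0, config.gene_sigma))
    v_max = float(np.clip(v_max, 1e-6, 1.0))
    v_min = float(np.clip(v_min, 0.0, v_max))
    return Chromosome(tuple(bool(b) for b in mask), v_max, v_min)


def run_ga(dataset: DescriptorDataset, config: GAConfig) -> GAHistory:
    """Run the GA search; returns the full per-generation history."""
    n_desc = len(dataset.descriptor_names)
    rng = np.random.default_rng(config.seed)
    seed_pool = np.random.SeedSequence(config.seed).spawn(
        config.n_generations * config.population_size
    )

    def train_seed(gen: int, idx: int) -> int:
        return int(seed_pool[gen * config.population_size + idx].generate_state(1)[0]
                   % (2**31))

    population = [_random_chromosome(n_desc, rng) for _ in range(config.population_size)]
    history = GAHistory()
    elite: EvaluatedChromosome | None = None
    for gen in range(config.n_generations):
        evaluated = []
        for i, ch in enumerate(population):
            # the elite carries its evaluation over unchanged, so the best
            # criterion value is non-decreasing across generations
            if i == 0 and elite is not None and ch == elite.chromosome:
                evaluated.append(elite)
            else:
                evaluated.append(
                    evaluate_chromosome(ch, dataset, config, train_seed(gen, i), gen)
                )
        evaluated.sort(key=lambda e: -e.criterion_value)
        history.generations.append(evaluated)
        elite = evaluated[0]
        if gen == config.n_generations - 1:
            break
        parents = [e.chromosome for e in evaluated[: config.n_crossover_parents]]
        nxt = [elite.chromosome]  # elitism
        while len(nxt) < config.population_size:
            i, j = rng.integers(len(parents)), rng.integers(len(parents))
            child = _crossover(parents[int(i)], parents[int(j)], rng)
            nxt.append(_mutate(child, config, rng))
        population = nxt
    return history


def _passes_rule1(stats: dict[str, dict[str, float]]) -> bool:
    for part in ("TR", "TE1", "TE2"):
        if part not in stats:
            return False
        if stats[part]["sens"] < SENS_SPEC_THRESHOLD:
            return False
        if stats[part]["spec"] < SENS_SPEC_THRESHOLD:
            return False
        if stats[part]["mcc"] < MCC_THRESHOLD:
            return False
    return True


def accept_models(history: GAHistory) -> list[EvaluatedChromosome]:
    """Select candidate models from a GA history.

    Rule 1 keeps every evaluated model meeting the sensitivity/specificity
    and MCC thresholds on TR, TE1 and TE2.  Rule 2 (only when the history
    spans at least 20 generations): each best-of-generation rank slot
    (1st, 2nd, 3rd) is averaged over the final 20 generations; if any slot
    averages sensitivity and specificity >= 0.7 on all three sets, the three
    best chromosomes of the final generation are selected too.  Duplicates
    are returned once.
    """
    selected: list[EvaluatedChromosome] = []
    seen: set[int] = set()
    for gen in history.generations:
        for e in gen:
            if _passes_rule1(e.stats) and id(e) not in seen:
                selected.append(e)
                seen.add(id(e))

    if history.n_generations >= BEST3_WINDOW:
        top3 = history.best_per_generation(3)[-BEST3_WINDOW:]
        fires = False
        for slot in range(3):
            ok = True
            for part in ("TR", "TE1", "TE2"):
                vals_s = [g[slot].stats[part]["sens"] for g in top3 if len(g) > slot
                          and part in g[slot].stats]
                vals_p = [g[slot].stats[part]["spec"] for g in top3 if len(g) > slot
                          and part in g[slot].stats]
                if not vals_s or np.mean(vals_s) < SENS_SPEC_THRESHOLD \
                        or np.mean(vals_p) < SENS_SPEC_THRESHOLD:
                    ok = False
                    break
            if ok:
                fires = True
                break
        if fires:
            for e in history.best_per_generation(3)[-1]:
                if id(e) not in seen:
                    selected.append(e)
                    seen.add(id(e))
    return selected


def stability_check(
    candidate: EvaluatedChromosome,
    dataset: DescriptorDataset,
    config: GAConfig,
    n_retrains: int = 100,
    seed: int = 0,
) -> AcceptanceReport:
    """Retrain a candidate under ``n_retrains`` seeded object orders.

    Descriptors and hyper-parameters are fixed; only the training seed (and
    hence object order / subsample draws) varies.  Accepted iff mean
    sensitivity and mean specificity are >= 0.7 on TR, TE1 and TE2.
    """
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(n_retrains)]
    runs = [
        evaluate_chromosome(candidate.chromosome, dataset, config, s)
        for s in seeds
    ]
    parts = [p for p in ("TR", "TE1", "TE2") if p in runs[0].stats]
    mean: dict[str, dict[str, float]] = {}
    sd: dict[str, dict[str, float]] = {}
    for part in parts:
        mean[part] = {}
        sd[part] = {}
        for m in ("sens", "spec", "mcc"):
            vals = np.array([r.stats[part][m] for r in runs])
            mean[part][m] = float(vals.mean())
            sd[part][m] = float(vals.std())
    accepted = all(
        mean[part][m] >= SENS_SPEC_THRESHOLD
        for part in ("TR", "TE1", "TE2") if part in mean
        for m in ("sens", "spec")
    ) and all(p in mean for p in ("TR", "TE1", "TE2"))
    return AcceptanceReport(candidate.chromosome, n_retrains, mean, sd, accepted)
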