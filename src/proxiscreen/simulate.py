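"""Synthetic dual-assay data with known ground truth.

Two generators emulate the statistical structure of the study design that the
rest of the package analyses:

``simulate_bioid``
    Label-free peptide quantification of streptavidin-captured,
    proximity-biotinylated proteins.  Baits are a promiscuous biotin ligase
    (BirA*) alone (the background control) and BirA* fused to the oncogenic
    RAS isoforms, transfected in triplicate.  Protein abundances are
    heavy-tailed (log-normal baselines), replicate noise is multiplicative
    log-normal with a configurable coefficient of variation, and each
    protein's signal is split over a fixed set of peptides.  Endogenously
    biotinylated carboxylases, the ligase itself, and RAF-family positive
    controls are planted as reference proteins.

``simulate_screen``
    A pooled CRISPR-Cas9 dropout screen: five guides per gene with variable
    efficacy, essential ribosomal-gene and non-targeting controls, grown in
    four genetic backgrounds (empty vector plus the three RAS oncogenes) and
    sequenced at three timepoints in triplicate.  Guide abundance follows an
    exponential-growth model, counts are negative-binomial (gamma-Poisson).

Random streams are keyed per entity id, so enlarging a simulation does not
perturb the draws of entities already present.  Every output is a plain
pandas DataFrame writable as TSV.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ReferenceProteins",
    "BioidSimConfig",
    "ScreenSimConfig",
    "BioidSim",
    "ScreenSim",
    "simulate_bioid",
    "simulate_screen",
    "default_screen_fitness",
]


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


def _entity_rng(seed: int, *keys) -> np.random.Generator:
    """Generator keyed by ``(seed, *keys)``.

    The key tuple is hashed, so streams for distinct entities are
    independent and stable under changes elsewhere in the configuration.
    """
    token = "\x1f".join(str(k) for k in keys).encode()
    digest = hashlib.blake2b(token, digest_size=8).digest()
    word = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), word]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV.

    ``cv == 0`` returns exactly 1 so the noise-free limit is exact.
    """
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


# ---------------------------------------------------------------------------
# BioID arm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceProteins:
    """Planted reference proteins and their assigned bait folds.

    carboxylase : endogenously biotinylated carboxylases, captured equally in
        every sample (fold 1); used as pull-down normalizers.
    bira : the ligase itself, present in every sample.
    raf : RAF-family positive controls mapped to the fold with which each is
        enriched by every RAS bait over the ligase-only control.  The least
        enriched of these drives the stringency calibration downstream.
    """

    carboxylase: tuple[str, ...] = ("PC", "PCCA", "MCCC1")
    bira: tuple[str, ...] = ("BirA",)
    raf: Mapping[str, float] = field(
        default_factory=lambda: {"ARAF": 4.0, "BRAF": 3.0, "RAF1": 2.5}
    )

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.carboxylase + self.bira + tuple(self.raf)


@dataclass
class BioidSimConfig:
    """Configuration of the proximity-labeling simulation.

    Parameters mirror the experimental design: ``baits`` lists the ligase-only
    control first, ``replicates_per_bait`` transfection replicates each, and a
    QC pool (an equal mixture of all samples) injected ``n_qc_samples`` times.
    ``n_true_per_bait`` plants that many anonymous interactors per bait, a
    ``shared_interactor_fraction`` of the union being labeled by two or three
    baits.  ``spiked`` plants named interactors with explicit per-bait folds
    (default: a KRAS-specific interactor at the global ``true_fold``).
    ``conditions`` multiplies selected proteins in knockout/knockdown sample
    groups, for differential-labeling experiments.
    """

    n_proteins: int = 2000
    n_true_per_bait: Mapping[str, int] = field(
        default_factory=lambda: {"KRAS": 100, "NRAS": 100, "HRAS": 100}
    )
    shared_interactor_fraction: float = 0.75
    true_fold: float = 4.0
    replicate_cv: float = 0.10
    peptides_per_protein: tuple[str, float] = ("one_plus_poisson", 7.0)
    baits: tuple[str, ...] = ("control", "KRAS", "NRAS", "HRAS")
    replicates_per_bait: int = 3
    reference_proteins: ReferenceProteins = field(default_factory=ReferenceProteins)
    spiked: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"PIP5K1A": {"KRAS": 4.0}}
    )
    conditions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"vector": {}}
    )
    n_qc_samples: int = 3
    baseline_meanlog: float = 15.0
    baseline_sdlog: float = 1.5
    reference_abundance_boost: float = 30.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_fold <= 0:
            raise ConfigError("true_fold must be positive")
        if self.replicate_cv < 0:
            raise ConfigError("replicate_cv must be non-negative")
        if self.replicates_per_bait < 2:
            raise ConfigError("need at least 2 replicates per bait")
        if not 0.0 <= self.shared_interactor_fraction <= 1.0:
            raise ConfigError("shared_interactor_fraction must be in [0, 1]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        for prot, folds in self.spiked.items():
            for bait, f in folds.items():
                if f <= 0:
                    raise ConfigError(f"spiked fold for {prot}/{bait} must be positive")
        for ref, f in self.reference_proteins.raf.items():
            if f <= 0:
                raise ConfigError(f"reference fold for {ref} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "BioidSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "reference_proteins" in raw:
            rp = raw["reference_proteins"]
            raw["reference_proteins"] = ReferenceProteins(
                carboxylase=tuple(rp.get("carboxylase", ("PC", "PCCA", "MCCC1"))),
                bira=tuple(rp.get("bira", ("BirA",))),
                raf=dict(rp.get("raf", {"ARAF": 4.0, "BRAF": 3.0, "RAF1": 2.5})),
            )
        if "peptides_per_protein" in raw:
            raw["peptides_per_protein"] = tuple(raw["peptides_per_protein"])
        if "baits" in raw:
            raw["baits"] = tuple(raw["baits"])
        return cls(**raw)


@dataclass
class BioidSim:
    """Outputs of :func:`simulate_bioid`."""

    peptides: pd.DataFrame  # protein_id, peptide_id, one column per sample
    samples: pd.DataFrame   # sample_id, bait, condition, replicate, is_qc
    truth: pd.DataFrame     # entity_id, kind, fold_<bait> columns


def _n_peptides(spec: tuple[str, float], rng: np.random.Generator) -> int:
    kind, param = spec
    if kind == "constant":
        return max(1, int(param))
    if kind == "one_plus_poisson":
        return 1 + int(rng.poisson(param))
    if kind == "geometric":
        # param = success probability; support {1, 2, ...}
        return int(rng.geometric(param))
    raise ConfigError(f"unknown peptides_per_protein spec {kind!r}")


def _interactor_memberships(config: BioidSimConfig, ids: list[str]) -> dict[str, set[str]]:
    """Assign anonymous true interactors to baits.

    Greedy quota filling: each new union member is a single-bait interactor
    with probability ``1 - shared_interactor_fraction``, otherwise it is
    assigned to two or three baits (chosen among baits with remaining quota).
    Per-bait counts therefore match ``n_true_per_bait`` closely but not
    always exactly when sharing is high; the truth table is exact.
    """
    rng = _entity_rng(config.seed, "bioid-truth")
    quota = {b: int(n) for b, n in config.n_true_per_bait.items() if n > 0}
    for b in quota:
        if b not in config.baits:
            raise ConfigError(f"n_true_per_bait bait {b!r} not in baits")
    members: dict[str, set[str]] = {}
    pool = iter(ids)
    while any(n > 0 for n in quota.values()):
        open_baits = [b for b, n in quota.items() if n > 0]
        try:
            pid = next(pool)
        except StopIteration:
            raise ConfigError("n_proteins too small for requested interactor counts")
        if len(open_baits) == 1 or rng.random() >= config.shared_interactor_fraction:
            chosen = [rng.choice(open_baits)]
        else:
            k = min(len(open_baits), int(rng.choice([2, 3])))
            chosen = list(rng.choice(open_baits, size=k, replace=False))
        members[pid] = set(chosen)
        for b in chosen:
            quota[b] -= 1
    return members


def simulate_bioid(config: BioidSimConfig) -> BioidSim:
    """Generate a peptide quantification table with known ground truth.

    The intensity of protein *p* in sample *s* is
    ``baseline(p) * fold(p, bait(s)) * condition_multiplier(p, s) * noise``,
    with multiplicative log-normal noise of CV ``replicate_cv``, split over
    the protein's peptides with fixed per-protein weights.  QC-pool samples
    are the per-protein mean of all biological samples times fresh technical
    noise at the same CV.  Deterministic given the seed.
    """
    baits = list(config.baits)
    control = baits[0]
    anon_ids = [f"P{i + 1:04d}" for i in range(config.n_proteins)]
    ref = config.reference_proteins
    named = list(config.spiked) + list(ref.all_ids)
    clash = set(named) & set(anon_ids)
    if clash:
        raise ConfigError(f"named protein ids clash with anonymous pool: {sorted(clash)}")

    members = _interactor_memberships(config, anon_ids)

    # fold map: protein -> bait -> fold (missing -> 1)
    folds: dict[str, dict[str, float]] = {}
    kinds: dict[str, str] = {}
    for pid in anon_ids:
        if pid in members:
            folds[pid] = {b: config.true_fold for b in members[pid]}
            kinds[pid] = "interactor"
        else:
            folds[pid] = {}
            kinds[pid] = "null"
    for pid, per_bait in config.spiked.items():
        folds[pid] = dict(per_bait)
        kinds[pid] = "spiked"
    ras_baits = [b for b in baits if b != control]
    for pid in ref.carboxylase:
        folds[pid] = {}
        kinds[pid] = "carboxylase"
    for pid in ref.bira:
        folds[pid] = {}
        kinds[pid] = "bira"
    for pid, f in ref.raf.items():
        folds[pid] = {b: f for b in ras_baits}
        kinds[pid] = "raf_control"

    # samples: every (bait, condition, replicate); QC pools appended
    sample_rows = []
    for bait in baits:
        for cond in config.conditions:
            for r in range(1, config.replicates_per_bait + 1):
                sid = f"{bait}.{cond}.r{r}" if len(config.conditions) > 1 else f"{bait}_r{r}"
                sample_rows.append((sid, bait, cond, r, False))
    for q in range(1, config.n_qc_samples + 1):
        sample_rows.append((f"QC_r{q}", "QC", "qc_pool", q, True))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "bait", "condition", "replicate", "is_qc"]
    )
    bio = samples[~samples.is_qc]
    n_bio, n_qc = len(bio), config.n_qc_samples

    all_ids = anon_ids + named
    prot_rows, pep_rows, data_blocks = [], [], []
    for pid in all_ids:
        rng = _entity_rng(config.seed, "bioid", pid)
        base = float(np.exp(rng.normal(config.baseline_meanlog, config.baseline_sdlog)))
        if kinds[pid] in ("carboxylase", "bira"):
            base *= config.reference_abundance_boost
        k = _n_peptides(config.peptides_per_protein, rng)
        weights = rng.dirichlet(np.ones(k))
        pf = folds[pid]
        means = np.empty(n_bio)
        for j, (_, row) in enumerate(bio.iterrows()):
            mult = config.conditions.get(row.condition, {}).get(pid, 1.0)
            means[j] = base * pf.get(row.bait, 1.0) * mult
        noise = _lognormal_factor(rng, config.replicate_cv, size=n_bio)
        intens = means * noise
        pool_mean = intens.mean()
        qc_noise = _lognormal_factor(rng, config.replicate_cv, size=n_qc)
        qc_intens = pool_mean * qc_noise
        full = np.concatenate([intens, qc_intens])
        if config.dropout_rate > 0:
            drop = rng.random(full.size) < config.dropout_rate
            full = np.where(drop, 0.0, full)
        block = np.outer(weights, full)  # peptides x samples
        for i in range(k):
            prot_rows.append(pid)
            pep_rows.append(f"{pid}.pep{i + 1}")
        data_blocks.append(block)

    data = np.vstack(data_blocks)
    peptides = pd.DataFrame(data, columns=list(samples.sample_id))
    peptides.insert(0, "peptide_id", pep_rows)
    peptides.insert(0, "protein_id", prot_rows)

    truth = pd.DataFrame({"entity_id": all_ids})
    truth["kind"] = [kinds[p] for p in all_ids]
    for b in baits:
        truth[f"fold_{b}"] = [folds[p].get(b, 1.0) for p in all_ids]
    return BioidSim(peptides=peptides, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# CRISPR screen arm
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Configuration of the pooled dropout-screen simulation.

    The relative mass of guide *g* at timepoint *t* in background *B* is
    ``baseline(g) * 2 ** (fitness(gene(g), B) * efficacy(g) * generations(t))``;
    frequencies renormalize within each sample and counts are drawn
    negative-binomially at the configured depth and dispersion (``dispersion
    == 0`` yields the rounded deterministic expectation).

    ``fitness`` maps gene -> background -> per-generation log2 fitness effect
    for target genes; ``None`` builds the default study conditions via
    :func:`default_screen_fitness` (one planted background-specific essential
    gene, all other target genes with small background-independent effects).
    Ribosomal controls are essential everywhere; their realized cost is
    weaker in the slowly proliferating vector background.  Non-targeting
    guides have fitness 0 by construction.
    """

    n_genes: int = 500
    guides_per_gene: int = 5
    n_ribosomal_controls: int = 50
    n_nontargeting: int = 100
    backgrounds: tuple[str, ...] = ("vector", "KRAS", "NRAS", "HRAS")
    timepoints: tuple[str, ...] = ("T0", "T1", "T2")
    replicates: int = 3
    depth: float = 2e6
    depth_jitter_cv: float = 0.0
    dispersion: float = 0.05
    genes: Sequence[str] | None = None
    fitness: Mapping[str, Mapping[str, float]] | None = None
    ribosomal_fitness: Mapping[str, float] = field(
        default_factory=lambda: {"vector": -0.6, "KRAS": -0.8, "NRAS": -0.8, "HRAS": -0.8}
    )
    generations_per_timepoint: Mapping[str, float] = field(
        default_factory=lambda: {"T0": 0.0, "T1": 3.0, "T2": 8.0}
    )
    efficacy_beta: tuple[float, float] = (5.0, 2.0)
    baseline_sdlog: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be non-negative")
        if self.guides_per_gene < 1:
            raise ConfigError("guides_per_gene must be >= 1")
        for b, f in self.ribosomal_fitness.items():
            if f >= 0:
                raise ConfigError(f"ribosomal fitness in {b!r} must be negative")
        missing = [b for b in self.backgrounds if b not in self.ribosomal_fitness]
        if missing:
            raise ConfigError(f"ribosomal_fitness missing backgrounds: {missing}")
        missing_t = [t for t in self.timepoints if t not in self.generations_per_timepoint]
        if missing_t:
            raise ConfigError(f"generations_per_timepoint missing: {missing_t}")

    @classmethod
    def from_yaml(cls, path) -> "ScreenSimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("backgrounds", "timepoints", "efficacy_beta"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ScreenSim:
    """Outputs of :func:`simulate_screen`."""

    counts: pd.DataFrame   # guide_id column + one integer column per sample
    library: pd.DataFrame  # guide_id, gene, class
    samples: pd.DataFrame  # sample_id, background, timepoint, replicate
    truth: pd.DataFrame    # guide_id, gene, class, efficacy, fitness_<background>


def default_screen_fitness(
    genes: Sequence[str],
    backgrounds: Sequence[str],
    seed: int,
    planted_gene: str = "PIP5K1A",
    planted_background: str = "KRAS",
    planted_fitness: float = -0.8,
    null_fitness_range: float = 0.2,
) -> dict[str, dict[str, float]]:
    """Default fitness map: one planted background-specific essential gene.

    Every other target gene receives a background-independent fitness drawn
    uniformly from ``[-null_fitness_range, +null_fitness_range]`` — real but
    RAS-nonspecific growth effects that cancel in vector-referenced
    enrichment scores.
    """
    fitness: dict[str, dict[str, float]] = {}
    for g in genes:
        if g == planted_gene:
            fitness[g] = {planted_background: planted_fitness}
        else:
            rng = _entity_rng(seed, "fitness", g)
            f = float(rng.uniform(-null_fitness_range, null_fitness_range))
            fitness[g] = {b: f for b in backgrounds}
    return fitness


def simulate_screen(config: ScreenSimConfig) -> ScreenSim:
    """Generate guide count matrices over backgrounds x timepoints x replicates."""
    if config.genes is not None:
        genes = list(config.genes)
    else:
        genes = ["PIP5K1A"] + [f"G{i:04d}" for i in range(2, config.n_genes + 1)]
    ribo_genes = [f"RPL{i:04d}" for i in range(1, config.n_ribosomal_controls + 1)]
    nt_ids = [f"NT{i:04d}" for i in range(1, config.n_nontargeting + 1)]

    fitness = (
        {g: dict(v) for g, v in config.fitness.items()}
        if config.fitness is not None
        else default_screen_fitness(genes, config.backgrounds, config.seed)
    )
    for g in ribo_genes:
        fitness[g] = dict(config.ribosomal_fitness)

    lib_rows: list[tuple[str, str, str]] = []
    for g in genes:
        for j in range(1, config.guides_per_gene + 1):
            lib_rows.append((f"{g}_g{j}", g, "target"))
    for g in ribo_genes:
        for j in range(1, config.guides_per_gene + 1):
            lib_rows.append((f"{g}_g{j}", g, "ribosomal_control"))
    for gid in nt_ids:
        lib_rows.append((gid, gid, "nontargeting"))
    library = pd.DataFrame(lib_rows, columns=["guide_id", "gene", "class"])

    sample_rows = [
        (f"{b}_{t}_r{r}", b, t, r)
        for b in config.backgrounds
        for t in config.timepoints
        for r in range(1, config.replicates + 1)
    ]
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "background", "timepoint", "replicate"]
    )
    n_samples = len(samples)

    n_guides = len(library)
    baselines = np.empty(n_guides)
    efficacies = np.empty(n_guides)
    for i, (gid, _gene, cls) in enumerate(lib_rows):
        rng = _entity_rng(config.seed, "guide", gid)
        baselines[i] = np.exp(rng.normal(0.0, config.baseline_sdlog))
        a, b = config.efficacy_beta
        if cls == "nontargeting" or b == 0:  # (a, 0) means all guides fully effective
            efficacies[i] = 1.0
        else:
            efficacies[i] = rng.beta(a, b)

    gens = np.array(
        [config.generations_per_timepoint[t] for t in samples.timepoint], dtype=float
    )
    fit = np.zeros((n_guides, n_samples))
    bkg_cols = {b: np.flatnonzero(samples.background.values == b) for b in config.backgrounds}
    for i, (_gid, gene, cls) in enumerate(lib_rows):
        if cls == "nontargeting":
            continue
        per_bkg = fitness.get(gene, {})
        for b, cols in bkg_cols.items():
            f = per_bkg.get(b, 0.0)
            if f:
                fit[i, cols] = f

    log2_mass = np.log2(baselines)[:, None] + fit * efficacies[:, None] * gens[None, :]
    mass = np.exp2(log2_mass - log2_mass.max(axis=0, keepdims=True))
    freq = mass / mass.sum(axis=0, keepdims=True)

    depth_rng = _entity_rng(config.seed, "depth")
    depths = config.depth * _lognormal_factor(depth_rng, config.depth_jitter_cv, n_samples)
    mu = freq * depths[None, :]

    if config.dispersion == 0:
        counts = np.rint(mu).astype(np.int64)
    else:
        shape = 1.0 / config.dispersion
        counts = np.empty_like(mu, dtype=np.int64)
        for i, (gid, _gene, _cls) in enumerate(lib_rows):
            rng = _entity_rng(config.seed, "counts", gid)
            lam = rng.gamma(shape, mu[i] * config.dispersion)
            counts[i] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, columns=list(samples.sample_id))
    counts_df.insert(0, "guide_id", library.guide_id.values)

    truth = library.copy()
    truth["efficacy"] = efficacies
    for b in config.backgrounds:
        truth[f"fitness_{b}"] = [
            0.0 if cls == "nontargeting" else fitness.get(gene, {}).get(b, 0.0)
            for gene, cls in zip(library.gene, library["class"])
        ]
    truth = truth.rename(columns={"guide_id": "entity_id"})
    return ScreenSim(counts=counts_df, library=library, samples=samples, truth=truth)
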