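"""Ground-truthed simulator for culture-enriched profiling experiments.

The simulator emulates the statistical structure the analysis assumes:

* a long-tail rank-abundance fecal community (log-normal by default),
* per-condition selective growth — each culture condition supports a sparse,
  random subset of the truly culturable OTUs, with log-normal growth factors
  so that low-abundance taxa can be amplified well above their fecal
  abundance on a selective plate,
* multinomial 16S sequencing at configurable depth for both the
  culture-independent (fecal) sample and each plate pool,
* storage perturbations (freezing, aerobic exposure) that knock out or damage
  part of the culturability matrix,
* no-growth / dead-DNA controls, and
* point-mutated isolate 16S sequences with exactly known identity to their
  parent reference.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ConditionSpec, OtuTable, SampleMetadata

__all__ = [
    "CommunityTruth",
    "CulturabilityMatrix",
    "PerturbationSpec",
    "SyntheticTruth",
    "Experiment",
    "NoGrowthError",
    "default_conditions",
    "generate_community",
    "generate_culturability",
    "simulate_sequencing",
    "plate_composition",
    "simulate_plate_pool",
    "simulate_no_growth_control",
    "apply_perturbation",
    "generate_reference_sequences",
    "generate_isolate_sequences",
    "assign_synthetic_taxonomy",
    "build_experiment",
    "simulate_study",
]


class NoGrowthError(RuntimeError):
    """Raised when a plate pool is requested for a condition nothing grows on."""


@dataclass
class CommunityTruth:
    """True relative abundances of the fecal community (sums to 1)."""

    otu_ids: list[str]
    true_abundance: np.ndarray
    model: str = "lognormal"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_abundance = np.asarray(self.true_abundance, dtype=float)
        if self.true_abundance.ndim != 1 or len(self.true_abundance) != len(self.otu_ids):
            raise ValueError("abundance vector must match otu_ids")
        if np.any(self.true_abundance <= 0):
            raise ValueError("abundances must be strictly positive")
        if abs(self.true_abundance.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)


@dataclass
class CulturabilityMatrix:
    """Non-negative growth factors, conditions x OTUs.

    An OTU is *truly culturable* iff it has a positive factor on at least one
    condition.
    """

    growth_factor: np.ndarray
    conditions: list[ConditionSpec]

    def __post_init__(self) -> None:
        self.growth_factor = np.asarray(self.growth_factor, dtype=float)
        if self.growth_factor.ndim != 2 or self.growth_factor.shape[0] != len(self.conditions):
            raise ValueError("growth_factor must be (n_conditions, n_otus)")
        if self.growth_factor.size and self.growth_factor.min() < 0:
            raise ValueError("growth factors must be non-negative")

    @property
    def culturable_mask(self) -> np.ndarray:
        return (self.growth_factor > 0).any(axis=0)

    def row(self, condition: ConditionSpec) -> np.ndarray:
        return self.growth_factor[self.conditions.index(condition)]


@dataclass
class PerturbationSpec:
    """Storage perturbation: which kind, how much of the matrix it touches."""

    kind: str  # "frozen" | "aerobic_exposed"
    magnitude: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.kind not in ("frozen", "aerobic_exposed"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("magnitude must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests."""

    community: CommunityTruth
    culturability: CulturabilityMatrix
    background_rate: float = 0.0

    def truly_culturable_ids(self) -> frozenset[str]:
        mask = self.culturability.culturable_mask
        return frozenset(o for o, m in zip(self.community.otu_ids, mask) if m)


@dataclass
class Experiment:
    """One donor's simulated experiment: table + metadata + retained truth."""

    table: OtuTable
    metadata: list[SampleMetadata]
    truth: SyntheticTruth


def default_conditions(
    n_media: int = 33, atmospheres: Sequence[str] = ("anaerobic", "aerobic")
) -> list[ConditionSpec]:
    """The study design grid: ``n_media`` media under each atmosphere."""
    media = [f"M{i + 1:02d}" for i in range(n_media)]
    return [ConditionSpec(m, a) for a in atmospheres for m in media]


# ---------------------------------------------------------------------------
# Community and culturability
# ---------------------------------------------------------------------------

def generate_community(
    n_otus: int,
    model: str = "lognormal",
    seed: int = 0,
    *,
    sigma: float = 2.0,
    mu: float = 0.0,
    alpha: float = 1.5,
    prefix: str = "OTU",
) -> CommunityTruth:
    """Draw a long-tail fecal community.

    ``lognormal`` draws i.i.d. log-normal(mu, sigma) masses and normalizes;
    at the default sigma = 2 a few OTUs dominate and the rest form a long
    tail, the shape seen in gut rank-abundance curves.  ``power_law`` is a
    deterministic Zipf-like curve (abundance ~ rank^-alpha).  OTU ids are
    assigned in rank order (OTU0001 is the most abundant).
    """
    if n_otus < 1:
        raise ValueError("n_otus must be >= 1")
    rng = np.random.default_rng(seed)
    if model == "lognormal":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        mass = rng.lognormal(mu, sigma, size=n_otus)
        params = {"mu": mu, "sigma": sigma}
    elif model == "power_law":
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        mass = np.arange(1, n_otus + 1, dtype=float) ** (-alpha)
        params = {"alpha": alpha}
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    mass = np.sort(mass)[::-1]
    abundance = mass / mass.sum()
    width = max(4, len(str(n_otus)))
    otu_ids = [f"{prefix}{i + 1:0{width}d}" for i in range(n_otus)]
    return CommunityTruth(otu_ids, abundance, model, params)


def generate_culturability(
    community: CommunityTruth,
    conditions: Sequence[ConditionSpec],
    frac_culturable: float = 0.75,
    selectivity: float = 4.0,
    *,
    seed: int = 0,
    abundance_bias: float = 0.5,
    growth_sigma: float = 1.5,
) -> CulturabilityMatrix:
    """Plant a conditions x OTUs growth-factor matrix.

    Exactly ``round(frac_culturable * n_otus)`` OTUs are truly culturable.
    Which OTUs those are is drawn with probability weights proportional to
    abundance**abundance_bias, reflecting the observation that the OTUs no
    medium recovers tend to sit in the rare tail of the community.  Each
    culturable OTU grows on any given condition with probability
    1/selectivity (at least one condition is guaranteed), with a log-normal
    growth factor — median 1, so roughly half of the positive factors amplify
    the OTU above its fecal abundance.
    """
    if not 0.0 <= frac_culturable <= 1.0:
        raise ValueError("frac_culturable must be in [0, 1]")
    if selectivity <= 0:
        raise ValueError("selectivity must be positive")
    if not conditions:
        raise ValueError("need at least one condition")
    conditions = list(conditions)
    rng = np.random.default_rng(seed)
    n = community.n_otus
    n_cond = len(conditions)
    k = int(round(frac_culturable * n))
    growth = np.zeros((n_cond, n))
    if k > 0:
        weights = community.true_abundance ** abundance_bias
        weights = weights / weights.sum()
        chosen = rng.choice(n, size=k, replace=False, p=weights)
        p_grow = min(1.0, 1.0 / selectivity)
        for j in chosen:
            mask = rng.random(n_cond) < p_grow
            if not mask.any():
                mask[rng.integers(n_cond)] = True
            growth[mask, j] = rng.lognormal(0.0, growth_sigma, size=int(mask.sum()))
    return CulturabilityMatrix(growth, conditions)


# ---------------------------------------------------------------------------
# Sequencing draws
# ---------------------------------------------------------------------------

def simulate_sequencing(abundance: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Multinomial sequencing draw: counts sum to ``depth``."""
    abundance = np.asarray(abundance, dtype=float)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    total = abundance.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError("abundances must sum to 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, abundance / total)


def plate_composition(
    community: CommunityTruth, growth_row: np.ndarray, background_rate: float = 0.0
) -> np.ndarray:
    """Expected plate-pool composition: abundance x growth, renormalized.

    ``background_rate`` mixes in the fecal profile itself, emulating DNA
    deposited on the plate rather than grown (dead-DNA background); default 0
    so OTUs with zero growth factor receive zero expected reads.
    """
    growth_row = np.asarray(growth_row, dtype=float)
    if growth_row.shape != community.true_abundance.shape:
        raise ValueError("growth_row length must equal n_otus")
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must be in [0, 1]")
    w = community.true_abundance * growth_row
    total = w.sum()
    if total == 0:
        if background_rate == 0:
            raise NoGrowthError("no growth on condition")
        return community.true_abundance.copy()
    profile = (1.0 - background_rate) * (w / total) + background_rate * community.true_abundance
    return profile / profile.sum()


def simulate_plate_pool(
    community: CommunityTruth,
    growth_row: np.ndarray,
    depth: int,
    seed: int,
    background_rate: float = 0.0,
) -> np.ndarray:
    """Sequence one plate pool: multinomial draw from the plate composition."""
    if depth == 0:
        # still validate the growth row
        plate_composition(community, growth_row, background_rate)
        return np.zeros(community.n_otus, dtype=np.int64)
    profile = plate_composition(community, growth_row, background_rate)
    return simulate_sequencing(profile, depth, seed)


def simulate_no_growth_control(
    community: CommunityTruth,
    depth: int,
    seed: int,
    background_profile: np.ndarray | None = None,
) -> np.ndarray:
    """Sequence a sterilized (no-growth) plate control.

    The default background is the fecal profile itself: DNA deposited on the
    plate with nothing growing, so the control resembles the fecal sample and
    differs maximally from any strongly selective plate pool.
    """
    profile = (
        community.true_abundance if background_profile is None else np.asarray(background_profile)
    )
    if depth == 0:
        return np.zeros(len(profile), dtype=np.int64)
    return simulate_sequencing(profile / profile.sum(), depth, seed)


def apply_perturbation(matrix: CulturabilityMatrix, spec: PerturbationSpec) -> CulturabilityMatrix:
    """Storage effect on culturability.

    A seeded fraction ``magnitude`` of the positive growth factors is altered:
    freezing kills the affected (condition, OTU) pairs outright (factor -> 0);
    aerobic exposure damages them (factor x 0.1).  magnitude 0 returns an
    identical matrix.
    """
    growth = matrix.growth_factor.copy()
    pos = np.argwhere(growth > 0)
    n_hit = int(round(spec.magnitude * len(pos)))
    if n_hit:
        rng = np.random.default_rng(spec.rng_seed)
        hit = pos[rng.choice(len(pos), size=n_hit, replace=False)]
        if spec.kind == "frozen":
            growth[hit[:, 0], hit[:, 1]] = 0.0
        else:  # aerobic_exposed
            growth[hit[:, 0], hit[:, 1]] *= 0.1
    return CulturabilityMatrix(growth, list(matrix.conditions))


# ---------------------------------------------------------------------------
# Isolate sequences
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def generate_reference_sequences(
    n: int, length: int, seed: int, prefix: str = "ref"
) -> list[tuple[str, str]]:
    """Random ACGT reference sequences (mutually unrelated)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        seq = "".join(rng.choice(_BASES, size=length))
        out.append((f"{prefix}{i + 1:03d}", seq))
    return out


def generate_isolate_sequences(
    references: Sequence[tuple[str, str]],
    n_isolates: int,
    divergence: float,
    seed: int,
    prefix: str = "iso",
) -> list[tuple[str, str, str, float]]:
    """Point-mutated copies of references with exactly known identity.

    Each isolate is a substitution-only mutant of a seeded-random parent with
    exactly ``round(divergence * length)`` substituted positions, so
    ``true_identity = 1 - substitutions / length`` is closed-form ground truth
    for the identity classifier.  Returns (id, sequence, parent_id,
    true_identity) tuples.
    """
    if not references:
        raise ValueError("references must be non-empty")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_isolates):
        parent_id, parent_seq = references[rng.integers(len(references))]
        seq = np.array(list(parent_seq))
        n_sub = int(round(divergence * len(seq)))
        if n_sub:
            positions = rng.choice(len(seq), size=n_sub, replace=False)
            for p in positions:
                options = [b for b in "ACGT" if b != seq[p]]
                seq[p] = options[rng.integers(len(options))]
        out.append(
            (f"{prefix}{i + 1:03d}", "".join(seq), parent_id, 1.0 - n_sub / len(seq))
        )
    return out


# ---------------------------------------------------------------------------
# Taxonomy and experiment assembly
# ---------------------------------------------------------------------------

_LINEAGES = [
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Faecalibacterium",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella",
    "k__Bacteria;p__Actinobacteria;c__Actinobacteria;o__Bifidobacteriales;f__Bifidobacteriaceae;g__Bifidobacterium",
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacteriales;f__Enterobacteriaceae;g__Escherichia",
    "k__Bacteria;p__Firmicutes;c__Negativicutes;o__Selenomonadales;f__Veillonellaceae;g__Veillonella",
    "k__Bacteria;p__Firmicutes;c__Erysipelotrichia;o__Erysipelotrichales;f__Erysipelotrichaceae;g__Holdemania",
]


def assign_synthetic_taxonomy(otu_ids: Sequence[str], seed: int = 0) -> dict[str, str]:
    """Assign each OTU a Greengenes-style lineage from a small gut panel."""
    rng = np.random.default_rng(seed)
    weights = np.array([0.25, 0.2, 0.15, 0.1, 0.08, 0.07, 0.08, 0.07])
    picks = rng.choice(len(_LINEAGES), size=len(otu_ids), p=weights / weights.sum())
    return {o: _LINEAGES[int(i)] for o, i in zip(otu_ids, picks)}


def build_experiment(
    community: CommunityTruth,
    culturability: CulturabilityMatrix,
    *,
    donor: str = "D1",
    independent_depth: int = 206_076,
    plate_depth: int = 100_000,
    seed: int = 0,
    storage: str = "fresh",
    background_rate: float = 0.0,
    include_independent: bool = True,
    taxonomy: dict[str, str] | None = None,
) -> Experiment:
    """Assemble one donor's full design: fecal sample + one pool per condition.

    The default depths match the study design this simulator emulates
    (~2 x 10^5 culture-independent reads, 10^5 reads per plate pool).  When
    ``storage`` is not ``fresh`` the culturability matrix passed in should
    already be perturbed; samples are labelled accordingly and the
    culture-independent sample is attached only to fresh experiments.
    """
    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    metadata: list[SampleMetadata] = []

    if include_independent and storage == "fresh":
        sid = f"{donor}.fecal"
        sample_ids.append(sid)
        rows.append(
            simulate_sequencing(
                community.true_abundance, independent_depth, int(rng.integers(2**31))
            )
        )
        metadata.append(
            SampleMetadata(sid, "culture_independent", donor, "", "none", "fresh")
        )

    for i, cond in enumerate(culturability.conditions):
        sid = f"{donor}.{cond.medium}.{cond.atmosphere}.{storage}"
        counts = simulate_plate_pool(
            community,
            culturability.growth_factor[i],
            plate_depth,
            int(rng.integers(2**31)),
            background_rate,
        )
        sample_ids.append(sid)
        rows.append(counts)
        metadata.append(
            SampleMetadata(sid, "plate_pool", donor, cond.medium, cond.atmosphere, storage)
        )

    table = OtuTable(sample_ids, community.otu_ids, np.vstack(rows), taxonomy)
    return Experiment(table, metadata, SyntheticTruth(community, culturability, background_rate))


def simulate_study(
    n_donors: int = 5,
    n_otus: int = 500,
    conditions: Sequence[ConditionSpec] | None = None,
    *,
    independent_depth: int = 206_076,
    plate_depth: int = 100_000,
    frac_culturable: float = 0.75,
    selectivity: float = 4.0,
    abundance_bias: float = 0.5,
    sigma: float = 2.0,
    seed: int = 0,
) -> tuple[OtuTable, list[SampleMetadata], dict[str, SyntheticTruth]]:
    """Simulate a multi-donor study over a shared OTU universe.

    Each donor gets an independent community draw and an independent
    culturability matrix (donor-specific selective growth), mirroring
    inter-individual heterogeneity.  Returns the combined table, combined
    metadata, and per-donor ground truth.
    """
    if conditions is None:
        conditions = default_conditions()
    root = np.random.default_rng(seed)
    otu_template = generate_community(n_otus, seed=int(root.integers(2**31)), sigma=sigma)
    taxonomy = assign_synthetic_taxonomy(otu_template.otu_ids, seed=int(root.integers(2**31)))
    tables: list[OtuTable] = []
    metadata: list[SampleMetadata] = []
    truths: dict[str, SyntheticTruth] = {}
    for d in range(n_donors):
        donor = f"D{d + 1}"
        community = generate_community(n_otus, seed=int(root.integers(2**31)), sigma=sigma)
        culturability = generate_culturability(
            community,
            conditions,
            frac_culturable,
            selectivity,
            seed=int(root.integers(2**31)),
            abundance_bias=abundance_bias,
        )
        exp = build_experiment(
            community,
            culturability,
            donor=donor,
            independent_depth=independent_depth,
            plate_depth=plate_depth,
            seed=int(root.integers(2**31)),
            taxonomy=taxonomy,
        )
        tables.append(exp.table)
        metadata.extend(exp.metadata)
        truths[donor] = exp.truth
    return OtuTable.concat(tables), metadata, truths
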