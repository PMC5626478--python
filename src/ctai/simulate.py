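"""Seeded synthetic data: tRNA pools, ORFs with planted low-adaptiveness
regions, and ctAI-linked noisy expression tables.

Every generator takes a scenario object holding its parameters and seed, uses
one private ``numpy.random.Generator`` (no global state), and is
bit-reproducible per seed.

What these emulate — and what they do not: pools reuse the measured
45-anticodon decoding repertoire as a structural template and only randomize
abundances (log-normal, parameters fitted to the measured counts), so decoding
biology is never invented; ORFs are codon-i.i.d. within two strata and lack
real codon-pair, GC and secondary-structure correlations; expression is a
noisy linear response to region ctAI, the simplest defensible stand-in for
relative mRNA levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adaptiveness import AdaptivenessTable, ConstraintTable, adaptiveness_from_map
from .errors import ScenarioError
from .fit import ExpressionTable
from .genetic_code import synonymous_codons
from .pool import AnticodonSpecies, PairingClass, TRNAPool, build_decoding_map
from .scoring import OrfSequence, Region, score_region

__all__ = [
    "PoolScenario",
    "OrfScenario",
    "ExpressionScenario",
    "simulate_pool",
    "simulate_orf_with_region",
    "simulate_expression",
    "simulate_wobble_constructs",
]

# log-normal fit (MLE) to the measured HEK293 anticodon read counts;
# central mass spans roughly 6e3..3e5 reads
DEFAULT_LOG_MEAN = 10.51
DEFAULT_LOG_SD = 0.93


@dataclass(frozen=True)
class PoolScenario:
    """Randomized-abundance pool on the canonical 45-anticodon template."""

    n_species: int = 45
    log_mean: float = DEFAULT_LOG_MEAN
    log_sd: float = DEFAULT_LOG_SD
    seed: int = 0

    def count_quantile(self, q: float) -> float:
        """Analytic quantile of the abundance model (before rounding)."""
        from scipy.stats import lognorm

        return float(lognorm.ppf(q, s=self.log_sd, scale=np.exp(self.log_mean)))


def _template_species() -> tuple[AnticodonSpecies, ...]:
    from .data import hek293_pool

    return hek293_pool().species


def simulate_pool(scenario: PoolScenario) -> TRNAPool:
    """Draw a complete pool: template decoding structure, log-normal counts.

    Counts are rounded to integers and clamped to a minimum of 1. The full
    45-species template is required for 61-codon coverage, so ``n_species``
    below the template size is a scenario error.
    """
    template = _template_species()
    if scenario.n_species < len(template):
        raise ScenarioError(
            f"n_species={scenario.n_species} below the {len(template)}-anticodon "
            "template minimum for full sense-codon coverage"
        )
    if scenario.n_species > len(template):
        raise ScenarioError(
            f"n_species={scenario.n_species} exceeds the canonical template "
            f"({len(template)} anticodon species)"
        )
    rng = np.random.default_rng(scenario.seed)
    counts = np.maximum(
        1, np.rint(rng.lognormal(scenario.log_mean, scenario.log_sd, len(template)))
    ).astype(int)
    species = tuple(
        AnticodonSpecies(
            anticodon=t.anticodon,
            amino_acid=t.amino_acid,
            read_count=int(c),
            decoded_codons=t.decoded_codons,
        )
        for t, c in zip(template, counts)
    )
    return TRNAPool(species)


@dataclass(frozen=True)
class OrfScenario:
    """ORF with a planted region of distinct mean codon adaptiveness."""

    total_len: int = 400
    region: Region = field(default_factory=lambda: Region(181, 260))
    region_target_w: float = 0.25
    background_target_w: float = 0.8
    tolerance: float = 0.05
    seed: int = 0


def _stratified_draw(
    rng: np.random.Generator,
    codons: list[str],
    w: np.ndarray,
    target: float,
    n: int,
    tolerance: float,
    max_tries: int = 500,
) -> list[str]:
    if not w.min() - tolerance <= target <= w.max() + tolerance:
        raise ScenarioError(
            f"target mean w {target} outside reachable range "
            f"[{w.min():.3f}, {w.max():.3f}]"
        )
    low = np.flatnonzero(w <= target)
    high = np.flatnonzero(w > target)
    if len(low) == 0 or len(high) == 0:
        pool_idx = low if len(low) else high
        for _ in range(max_tries):
            draw = rng.choice(pool_idx, size=n)
            if abs(w[draw].mean() - target) <= tolerance:
                return [codons[i] for i in draw]
        raise ScenarioError(f"could not realize mean w {target} ± {tolerance}")
    mean_low, mean_high = w[low].mean(), w[high].mean()
    alpha = np.clip((target - mean_low) / (mean_high - mean_low), 0.0, 1.0)
    for _ in range(max_tries):
        pick_high = rng.random(n) < alpha
        draw = np.where(pick_high, rng.choice(high, size=n), rng.choice(low, size=n))
        if abs(w[draw].mean() - target) <= tolerance:
            return [codons[i] for i in draw]
    raise ScenarioError(f"could not realize mean w {target} ± {tolerance}")


def simulate_orf_with_region(
    scenario: OrfScenario, table: AdaptivenessTable
) -> tuple[OrfSequence, Region]:
    """Sample an ORF whose planted region and background hit target mean w.

    Codons are drawn from w-stratified sense-codon sets and resampled until
    the realized means are within the scenario tolerance of their targets;
    the true planted region is returned for detector benchmarking.
    """
    scenario.region.check_within(scenario.total_len)
    rng = np.random.default_rng(scenario.seed)
    codons = sorted(table.w)
    w = np.array([table.w[c] for c in codons])
    region_n = len(scenario.region)
    background_n = scenario.total_len - region_n
    inside = _stratified_draw(
        rng, codons, w, scenario.region_target_w, region_n, scenario.tolerance
    )
    outside = _stratified_draw(
        rng, codons, w, scenario.background_target_w, background_n, scenario.tolerance
    )
    seq = (
        outside[: scenario.region.start - 1]
        + inside
        + outside[scenario.region.start - 1 :]
    )
    orf = OrfSequence(id=f"synthetic_orf_seed{scenario.seed}", codons=tuple(seq))
    return orf, scenario.region


@dataclass(frozen=True)
class ExpressionScenario:
    """Linear ctAI→expression response with additive Gaussian noise."""

    slope: float = 3.0
    intercept: float = 0.1
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def simulate_expression(
    region_scores: dict[str, float], scenario: ExpressionScenario
) -> ExpressionTable:
    """expression = slope × ctAI + intercept + N(0, sd), positive by resampling.

    Non-positive draws are redrawn (not truncated) so the noise stays
    symmetric away from zero.
    """
    if not region_scores:
        raise ValueError("no region scores supplied")
    rng = np.random.default_rng(scenario.seed)
    records = {}
    for cid in sorted(region_scores):
        mean = scenario.slope * region_scores[cid] + scenario.intercept
        value = mean + rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd else mean
        tries = 0
        while value <= 0:
            tries += 1
            if tries > 1000 or scenario.noise_sd == 0:
                raise ScenarioError(f"{cid}: cannot draw positive expression")
            value = mean + rng.normal(0.0, scenario.noise_sd)
        records[cid] = float(value)
    return ExpressionTable(records)


def simulate_wobble_constructs(
    pool: TRNAPool,
    n_constructs: int = 50,
    region_len: int = 72,
    constraints: ConstraintTable | None = None,
    seed: int = 0,
) -> tuple[dict[str, OrfSequence], Region, dict[str, float]]:
    """Construct panel spanning a gradient of wobble-U usage, for penalty
    recovery experiments.

    Each construct's region is drawn from the two-codon pyrimidine families in
    which a single G34 anticodon decodes both codons, taking the U-ending
    (wobble U:G) form with a construct-specific probability spaced over
    [0, 1]. Region ctAI under *constraints* (defaults) is returned as the
    ground truth used to generate expression.
    """
    constraints = constraints or ConstraintTable()
    decoding_map = build_decoding_map(pool)
    table = adaptiveness_from_map(decoding_map, constraints)
    pairs = []
    for codon in sorted(table.w):
        if codon[2] != "U":
            continue
        partner = codon[:2] + "C"
        if synonymous_codons(codon) != frozenset({codon, partner}):
            continue
        edges = dict(decoding_map.edges.get(codon, ()))
        if any(cls is PairingClass.UG for cls in edges.values()) and (
            decoding_map.anticodons_for(codon) & decoding_map.anticodons_for(partner)
        ):
            pairs.append((codon, partner))
    if not pairs:
        raise ScenarioError("pool has no single-anticodon U/C wobble families")
    rng = np.random.default_rng(seed)
    region = Region(1, region_len)
    constructs: dict[str, OrfSequence] = {}
    scores: dict[str, float] = {}
    for i in range(n_constructs):
        p_wobble = i / max(n_constructs - 1, 1)
        fam = rng.integers(len(pairs), size=region_len)
        use_u = rng.random(region_len) < p_wobble
        codons = tuple(pairs[f][0] if u else pairs[f][1] for f, u in zip(fam, use_u))
        cid = f"construct_{i:03d}"
        orf = OrfSequence(id=cid, codons=codons)
        constructs[cid] = orf
        scores[cid] = score_region(orf, region, table)
    return constructs, region, scores
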