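"""Seeded generator of COI-like barcode libraries with known ground truth.

The generator emulates the statistical structure of a densely sampled
regional beetle barcode library: strong AT bias concentrated at third
codon positions, shallow intraspecific divergence (~0.5% mean K2P),
deep divergence to the nearest heterospecific neighbor (~12%), and the
long-tailed specimens-per-species distribution typical of such surveys.
Species sit on a star phylogeny (each species ancestor evolves
independently from one library root for half the interspecific scale;
individuals radiate from the species ancestor for half the intraspecific
scale) — the downstream analyses consume distances, not genealogies, so
no coalescent machinery is needed.

Three anomaly classes can be injected with exact, verifiable ground
truth: haplotype-sharing species pairs (identification failures), deep
intraspecific splits (BIN splits / overlooked species) and singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .io_formats import (
    INVERTEBRATE_MITO,
    Library,
    SpecimenRecord,
    stop_codons,
)

GENERATOR_VERSION = "1.0"

#: Specimens-per-species distribution of a regional survey: species counts
#: 562, 427, 331, 219, 171, 98, 35, 15, 2, 2 for 1..10 specimens plus a
#: 10-species ">10" bucket (represented here as n=12), out of 1872 species.
SURVEY_SAMPLE_SIZE_COUNTS: dict[int, int] = {
    1: 562, 2: 427, 3: 331, 4: 219, 5: 171,
    6: 98, 7: 35, 8: 15, 9: 2, 10: 2, 12: 10,
}


def _normalize(counts: Mapping[int, float]) -> dict[int, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


#: GC content targets by codon position (fractions).  Position 3 carries
#: the strong AT bias (AT3 = 1 - 0.145 = 0.855); the three positions
#: average to an overall AT content of 0.66.
GC_BY_POSITION = (0.4486, 0.4250, 0.1451)
#: How GC splits into G vs C, and AT into A vs T (empirical COI skews).
G_FRACTION_OF_GC = 0.480
A_FRACTION_OF_AT = 0.448

_BASES = "ACGT"
_TS_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}  # A<->G, C<->T
_TV_PARTNERS = {0: (1, 3), 1: (0, 2), 2: (1, 3), 3: (0, 2)}


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the emulated survey's values."""

    n_species: int = 100
    sample_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: _normalize(SURVEY_SAMPLE_SIZE_COUNTS)
    )
    target_at_overall: float = 0.66
    target_at_pos3: float = 0.855
    kappa: float = 3.0
    interspecific_scale: float = 0.12
    intraspecific_scale: float = 0.005
    seq_length: int = 648
    n_shared_haplotype_pairs: int = 0
    n_deep_split_species: int = 0
    n_singleton_species: int = 0
    deep_split_depth: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = sum(self.sample_size_distribution.values())
        if abs(probs - 1.0) > 1e-9:
            raise ValueError("sample_size_distribution must sum to 1")
        for name in ("interspecific_scale", "intraspecific_scale"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.seq_length < 300 or self.seq_length % 3:
            raise ValueError("seq_length must be >= 300 and a codon multiple")
        needed = (2 * self.n_shared_haplotype_pairs
                  + self.n_deep_split_species + self.n_singleton_species)
        if needed > self.n_species:
            raise ValueError(
                f"anomaly counts need {needed} species but only "
                f"{self.n_species} are simulated"
            )


@dataclass
class GroundTruth:
    """What the generator actually did, for exact downstream verification."""

    species: list[str]
    shared_haplotype_components: list[tuple[str, ...]]
    deep_split_species: list[str]
    singleton_species: list[str]
    config: SimulationConfig
    generator_version: str = GENERATOR_VERSION


def position_frequencies(
    seq_length: int,
    gc_by_position: tuple[float, float, float] = GC_BY_POSITION,
) -> np.ndarray:
    """Per-site stationary base frequencies (seq_length x 4, ACGT order)."""
    freqs = np.empty((seq_length, 4))
    for pos in range(3):
        gc = gc_by_position[pos]
        at = 1.0 - gc
        row = np.array(
            [
                at * A_FRACTION_OF_AT,        # A
                gc * (1.0 - G_FRACTION_OF_GC),  # C
                gc * G_FRACTION_OF_GC,          # G
                at * (1.0 - A_FRACTION_OF_AT),  # T
            ]
        )
        freqs[pos::3] = row
    return freqs


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _stop_codon_codes(genetic_code: str) -> set[tuple[int, int, int]]:
    lut = {b: i for i, b in enumerate(_BASES)}
    return {
        (lut[c[0]], lut[c[1]], lut[c[2]]) for c in stop_codons(genetic_code)
    }


def random_root(
    rng: np.random.Generator,
    seq_length: int,
    freqs: Optional[np.ndarray] = None,
    genetic_code: str = INVERTEBRATE_MITO,
) -> np.ndarray:
    """Draw a stop-codon-free root sequence from the stationary frequencies."""
    if freqs is None:
        freqs = position_frequencies(seq_length)
    stops = _stop_codon_codes(genetic_code)
    out = np.empty(seq_length, dtype=np.int64)
    for i in range(seq_length):
        out[i] = rng.choice(4, p=freqs[i])
    for start in range(0, seq_length, 3):
        while tuple(out[start : start + 3]) in stops:
            for j in range(3):
                out[start + j] = rng.choice(4, p=freqs[start + j])
    return out


def evolve_sequence(
    parent: np.ndarray,
    branch_length: float,
    kappa: float = 3.0,
    rng: Optional[np.random.Generator] = None,
    target_freqs: Optional[np.ndarray] = None,
    avoid_stops_code: Optional[str] = None,
) -> np.ndarray:
    """Evolve a sequence under a continuous-time K2P process.

    ``branch_length`` is the expected number of substitution events per
    site.  Without ``target_freqs`` each site receives a Poisson number
    of events and each event replaces the base with a target weighted
    kappa-fold toward the transition partner — the pure K2P process.

    ``target_freqs`` (per-site stationary frequencies) switches to a
    reversible HKY-style chain with rates proportional to
    kappa(i,j) * pi(j): composition pressure is applied at the mutation
    proposal, so base composition stays stationary at the target
    frequencies instead of drifting toward uniform.  Time is scaled per
    site so the expected number of events at stationarity is still
    ``branch_length``.  ``avoid_stops_code`` names a genetic code;
    substitutions creating an internal stop codon (frame 0) are then
    reverted.  Both options perturb the pure K2P process and are off by
    default.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    child = parent.copy()
    if branch_length == 0:
        return child
    if target_freqs is None:
        n_events = rng.poisson(branch_length, size=child.size)
        weights = np.array([kappa, 1.0, 1.0])
        weights /= weights.sum()
        for site in np.flatnonzero(n_events):
            for _ in range(n_events[site]):
                cur = int(child[site])
                targets = (_TS_PARTNER[cur],) + _TV_PARTNERS[cur]
                child[site] = targets[rng.choice(3, p=weights)]
    else:
        _evolve_stationary(child, branch_length, kappa, target_freqs, rng)
    if avoid_stops_code is not None:
        _revert_stop_codons(child, parent, avoid_stops_code)
    return child


def _exit_rates(freqs: np.ndarray, kappa: float) -> np.ndarray:
    """Per-site total exit rate from each state under q(i->j) = k(i,j)pi(j)."""
    rates = np.empty_like(freqs)
    for i in range(4):
        ts = _TS_PARTNER[i]
        tv1, tv2 = _TV_PARTNERS[i]
        rates[:, i] = kappa * freqs[:, ts] + freqs[:, tv1] + freqs[:, tv2]
    return rates


def _evolve_stationary(
    child: np.ndarray,
    branch_length: float,
    kappa: float,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Site-wise Gillespie simulation of the pi-stationary chain (in place).

    Per-site time horizons are branch_length divided by the site's mean
    exit rate at stationarity, so expected events/site = branch_length.
    """
    exit_rates = _exit_rates(freqs, kappa)
    mean_rate = (freqs * exit_rates).sum(axis=1)
    remaining = branch_length / mean_rate
    active = np.arange(child.size)
    while active.size:
        rates = exit_rates[active, child[active]]
        dt = rng.exponential(1.0 / rates)
        jump = dt < remaining[active]
        jumping = active[jump]
        remaining[jumping] -= dt[jump]
        for site in jumping:
            cur = int(child[site])
            ts = _TS_PARTNER[cur]
            tv1, tv2 = _TV_PARTNERS[cur]
            w = np.array(
                [kappa * freqs[site, ts], freqs[site, tv1], freqs[site, tv2]]
            )
            child[site] = (ts, tv1, tv2)[rng.choice(3, p=w / w.sum())]
        active = jumping


def expected_k2p_proportions(d: float, kappa: float) -> tuple[float, float]:
    """Expected transition/transversion proportions at K2P distance ``d``."""
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    p = 0.25 + 0.25 * np.exp(-4.0 * beta * d) - 0.5 * np.exp(-2.0 * (alpha + beta) * d)
    q = 0.5 - 0.5 * np.exp(-4.0 * beta * d)
    return float(p), float(q)


def k2p_estimator_sd(d: float, kappa: float, n_sites: int) -> float:
    """Delta-method standard deviation of the K2P distance estimate."""
    p, q = expected_k2p_proportions(d, kappa)
    a = 1.0 / (1.0 - 2.0 * p - q)
    b = 0.5 * (a + 1.0 / (1.0 - 2.0 * q))
    var = (a * a * p * (1 - p) + b * b * q * (1 - q) - 2 * a * b * p * q) / n_sites
    return float(np.sqrt(max(var, 0.0)))


def _star_depth(config: SimulationConfig) -> float:
    """Half-distance of the species star, corrected for the NN minimum shift.

    ``interspecific_scale`` is the *expected nearest-neighbor distance*,
    but the NN is a minimum over S-1 noisy pairwise estimates and so sits
    below the typical pairwise distance by roughly sigma * sqrt(2 ln(S-1))
    (the expected extreme deviation of that many near-Gaussian draws,
    with sigma the delta-method SD of the K2P estimator at the target
    distance).  The star depth absorbs that shift up front so the
    realized mean NN tracks the configured scale.
    """
    s = config.n_species
    if s < 3:
        return config.interspecific_scale / 2.0
    sigma = k2p_estimator_sd(
        config.interspecific_scale, config.kappa, config.seq_length
    )
    shift = sigma * np.sqrt(2.0 * np.log(s - 1))
    return (config.interspecific_scale + shift) / 2.0


def _revert_stop_codons(
    child: np.ndarray, parent: np.ndarray, genetic_code: str
) -> None:
    """Revert substitutions that created an in-frame stop codon (in place)."""
    stops = _stop_codon_codes(genetic_code)
    for start in range(0, child.size - 2, 3):
        codon = tuple(child[start : start + 3])
        if codon in stops:
            for j in range(start, start + 3):
                if child[j] != parent[j]:
                    child[j] = parent[j]
                    if tuple(child[start : start + 3]) not in stops:
                        break


def simulate_library(config: Optional[SimulationConfig] = None
                     ) -> tuple[Library, GroundTruth]:
    """Generate a barcode library with ground truth.

    Species ancestors evolve from one composition-biased root for
    ``interspecific_scale / 2``; individuals radiate from their species
    ancestor for ``intraspecific_scale / 2`` each, so conspecific pairs
    diverge by about the intraspecific scale and heterospecific pairs by
    about the interspecific scale.  Anomalies are injected last:
    deep-split species receive a second subcluster whose ancestor sits
    ``deep_split_depth`` further away; sharing pairs copy one haplotype
    from the first species into one individual of the second; singletons
    are truncated to one individual.  Fully deterministic for a fixed
    seed.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    freqs = position_frequencies(config.seq_length)
    code = INVERTEBRATE_MITO
    root = random_root(rng, config.seq_length, freqs, code)

    sizes = np.array(sorted(config.sample_size_distribution), dtype=int)
    probs = np.array([config.sample_size_distribution[k] for k in sizes])

    n_sp = config.n_species
    width = len(str(n_sp))
    species_names = [f"Species_{i + 1:0{width}d}" for i in range(n_sp)]

    # assign anomaly roles to distinct species, deterministically
    role_order = rng.permutation(n_sp)
    cursor = 0
    singleton_ids = list(role_order[cursor : cursor + config.n_singleton_species])
    cursor += config.n_singleton_species
    deep_ids = list(role_order[cursor : cursor + config.n_deep_split_species])
    cursor += config.n_deep_split_species
    share_ids = [
        (role_order[cursor + 2 * i], role_order[cursor + 2 * i + 1])
        for i in range(config.n_shared_haplotype_pairs)
    ]
    deep_set = set(deep_ids)
    singleton_set = set(singleton_ids)

    records: list[SpecimenRecord] = []
    seqs_by_species: dict[int, list[np.ndarray]] = {}
    evolve_kw = dict(kappa=config.kappa, rng=rng, target_freqs=freqs,
                     avoid_stops_code=code)
    star_depth = _star_depth(config)
    for si, name in enumerate(species_names):
        ancestor = evolve_sequence(root, star_depth, **evolve_kw)
        if si in singleton_set:
            n_ind = 1
        else:
            n_ind = int(rng.choice(sizes, p=probs))
            if si in deep_set:
                n_ind = max(n_ind, 2)
        tip_depth = config.intraspecific_scale / 2.0
        seqs = []
        if si in deep_set:
            # two subclusters: the second radiates from a displaced ancestor
            n_b = max(1, n_ind // 2)
            alt = evolve_sequence(ancestor, config.deep_split_depth, **evolve_kw)
            parents = [ancestor] * (n_ind - n_b) + [alt] * n_b
        else:
            parents = [ancestor] * n_ind
        for parent in parents:
            seqs.append(evolve_sequence(parent, tip_depth, **evolve_kw))
        seqs_by_species[si] = seqs

    shared_components: list[tuple[str, ...]] = []
    for a, b in share_ids:
        # species b's first individual adopts a haplotype of species a
        seqs_by_species[b][0] = seqs_by_species[a][0].copy()
        shared_components.append((species_names[a], species_names[b]))

    for si, name in enumerate(species_names):
        for k, seq in enumerate(seqs_by_species[si], start=1):
            records.append(
                SpecimenRecord(
                    specimen_id=f"{name}_ind{k:02d}",
                    species=name.replace("_", " "),
                    sequence=_decode(seq),
                )
            )

    library = Library(records=records, aligned=True)
    truth = GroundTruth(
        species=[n.replace("_", " ") for n in species_names],
        shared_haplotype_components=[
            tuple(n.replace("_", " ") for n in comp) for comp in shared_components
        ],
        deep_split_species=sorted(
            species_names[i].replace("_", " ") for i in deep_ids
        ),
        singleton_species=sorted(
            species_names[i].replace("_", " ") for i in singleton_ids
        ),
        config=config,
    )
    return library, truth


def scenario_fixtures(seq_length: int = 648, seed: int = 2014
                      ) -> dict[str, Library]:
    """Deterministic mini-libraries for the recurring anomaly scenarios.

    ``clean_pair``: two well-separated species, clear barcode gap.
    ``trio_sharing``: three species all carrying one shared haplotype
    (plus one private variant each) — three identification failures.
    ``three_bin_split``: one species whose specimens form three clusters
    more than 2.2% apart — a three-way BIN split.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    freqs = position_frequencies(seq_length)
    code = INVERTEBRATE_MITO
    kw = dict(kappa=3.0, rng=rng, target_freqs=freqs, avoid_stops_code=code)

    def rec(sid: str, species: str, seq: np.ndarray) -> SpecimenRecord:
        return SpecimenRecord(specimen_id=sid, species=species,
                              sequence=_decode(seq))

    fixtures: dict[str, Library] = {}

    root = random_root(rng, seq_length, freqs, code)
    a = evolve_sequence(root, 0.06, **kw)
    b = evolve_sequence(root, 0.06, **kw)
    fixtures["clean_pair"] = Library(
        records=[
            rec("cp_a1", "Alpha one", a),
            rec("cp_a2", "Alpha one", evolve_sequence(a, 0.002, **kw)),
            rec("cp_b1", "Beta two", b),
            rec("cp_b2", "Beta two", evolve_sequence(b, 0.002, **kw)),
        ],
        aligned=True,
    )

    shared = random_root(rng, seq_length, freqs, code)
    fixtures["trio_sharing"] = Library(
        records=[
            rec("tr_x1", "Trio x", shared),
            rec("tr_x2", "Trio x", evolve_sequence(shared, 0.002, **kw)),
            rec("tr_y1", "Trio y", shared),
            rec("tr_y2", "Trio y", evolve_sequence(shared, 0.002, **kw)),
            rec("tr_z1", "Trio z", shared),
            rec("tr_z2", "Trio z", evolve_sequence(shared, 0.002, **kw)),
        ],
        aligned=True,
    )

    anc = random_root(rng, seq_length, freqs, code)
    c1 = evolve_sequence(anc, 0.025, **kw)
    c2 = evolve_sequence(anc, 0.025, **kw)
    c3 = evolve_sequence(anc, 0.025, **kw)
    fixtures["three_bin_split"] = Library(
        records=[
            rec("sp_c1a", "Splitter sp", c1),
            rec("sp_c1b", "Splitter sp", evolve_sequence(c1, 0.001, **kw)),
            rec("sp_c2a", "Splitter sp", c2),
            rec("sp_c2b", "Splitter sp", evolve_sequence(c2, 0.001, **kw)),
            rec("sp_c3a", "Splitter sp", c3),
            rec("sp_c3b", "Splitter sp", evolve_sequence(c3, 0.001, **kw)),
        ],
        aligned=True,
    )
    return fixtures
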