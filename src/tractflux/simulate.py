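"""Synthetic fluctuation-assay and resistant-clone data with known ground truth.

This module generates the two kinds of raw data the analysis pipeline
consumes:

* per-culture colony counts distributed according to the classical
  Luria--Delbrueck model (random mutation during exponential growth,
  mutant clones keep growing, hence heavy-tailed "jackpot" counts), plus
  binomial selective plating and Poisson nonselective titering;
* fragment lengths of 5-FOA-resistant clones under a configurable
  mutational-event spectrum, passed through a reporter-selection model
  (frameshift or trinucleotide-expansion) and Gaussian capillary sizing
  noise.

Model assumptions are the minimal classical ones: mutant relative fitness
1, no cell death, no reverse mutation, deterministic total growth, no
phenotypic lag.  All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .rates import CultureObservation, FluctuationExperiment

__all__ = [
    "LDParams",
    "AssayDesign",
    "SpectrumModel",
    "CloneRecord",
    "UnselectableSpectrumError",
    "TRACT_DESIGNS",
    "ld_pmf",
    "sample_mutant_counts",
    "simulate_culture_forward",
    "forward_culture_stats",
    "sample_forward_lea_coulson",
    "simulate_fluctuation_assay",
    "apply_reporter_selection",
    "simulate_resistant_clones",
]

# "coding_hit" marks reporter inactivation outside the tract (URA3 coding
# sequence); its tract delta is 0 by definition.
CODING_HIT = "coding_hit"

ClassKey = Union[int, str]


class UnselectableSpectrumError(ValueError):
    """No event class in the spectrum can pass reporter selection."""


@dataclass(frozen=True)
class LDParams:
    """Parameters of one Luria--Delbrueck culture ensemble.

    ``mu`` is the per-division mutation probability, ``n0``/``nt`` the
    initial and final cell counts (growth is deterministic), and the two
    fractions describe how much of each culture is plated selectively and
    how strongly it is diluted for the nonselective titer.  Defaults follow
    the convention of a 2 ml stationary culture: nt = 2e8 cells grown from
    a small inoculum, everything plated on 5-FOA, a 1e-6 dilution titered.
    """

    mu: float
    n0: float = 1e3
    nt: float = 2e8
    sel_plating_fraction: float = 1.0
    ns_dilution_fraction: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.mu < 1):
            raise ValueError(f"mu must be in (0, 1), got {self.mu}")
        if not (1 <= self.n0 < self.nt):
            raise ValueError(f"need 1 <= n0 < nt, got n0={self.n0}, nt={self.nt}")
        for name in ("sel_plating_fraction", "ns_dilution_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not math.isfinite(self.m):
            raise ValueError("m = mu*(nt - n0) must be finite")

    @property
    def m(self) -> float:
        """Expected number of mutation events per culture, mu*(nt - n0)."""
        return self.mu * (self.nt - self.n0)


@dataclass(frozen=True)
class AssayDesign:
    """Geometry and selection logic of one repeat-tract reporter assay.

    ``assay_type`` picks the selection rule: ``plasmid_frameshift`` selects
    net out-of-frame length changes of the in-frame tract upstream of URA3,
    ``chromosomal_tnr`` selects expansions of at least
    ``tnr_expansion_threshold_units`` repeat units (promoter trinucleotide
    assay), and ``control_forward`` selects only coding hits (random-sequence
    control, i.e. plain forward mutagenesis).
    """

    assay_type: str
    unit_bp: int
    ref_units: int
    flank_bp: float = 120.0
    tnr_expansion_threshold_units: int = 5

    _ASSAY_TYPES = ("plasmid_frameshift", "chromosomal_tnr", "control_forward")

    def __post_init__(self) -> None:
        if self.assay_type not in self._ASSAY_TYPES:
            raise ValueError(
                f"assay_type must be one of {self._ASSAY_TYPES}, got {self.assay_type!r}"
            )
        if self.unit_bp < 1:
            raise ValueError("unit_bp must be >= 1")
        if self.ref_units < 1:
            raise ValueError("ref_units must be >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.tnr_expansion_threshold_units < 1:
            raise ValueError("tnr_expansion_threshold_units must be >= 1")

    @property
    def ref_length_bp(self) -> float:
        """Amplicon length of the unmutated tract: flank + unit * ref_units."""
        return self.flank_bp + self.unit_bp * self.ref_units


#: The five tract designs assayed in the study system: a mononucleotide
#: (G)18 run, the (GT)49 microsatellite, a 25x trinucleotide promoter tract,
#: an 11 bp minisatellite x4 and a 20 bp minisatellite x3, plus the
#: random-sequence forward-mutagenesis control.  Flank lengths are
#: configuration (primer placement), not biological constants.
TRACT_DESIGNS: dict[str, AssayDesign] = {
    "mono_G18": AssayDesign("plasmid_frameshift", unit_bp=1, ref_units=18),
    "GT49": AssayDesign("plasmid_frameshift", unit_bp=2, ref_units=49),
    "TNR25": AssayDesign("chromosomal_tnr", unit_bp=3, ref_units=25, flank_bp=100.0),
    "11mer_x4": AssayDesign("plasmid_frameshift", unit_bp=11, ref_units=4),
    "20mer_x3": AssayDesign("plasmid_frameshift", unit_bp=20, ref_units=3),
    "control": AssayDesign("control_forward", unit_bp=1, ref_units=75),
}


@dataclass(frozen=True)
class SpectrumModel:
    """Ground-truth mutational-event spectrum for clone simulation.

    ``class_probs`` maps event classes to probabilities.  A class is either
    an integer tract delta in repeat units or the string ``"coding_hit"``
    (inactivating change outside the tract, tract delta 0).  Probabilities
    refer to mutational *events*; reporter selection then decides which
    events are recoverable as 5-FOA resistant clones.
    """

    design: AssayDesign
    class_probs: Mapping[ClassKey, float]
    sizing_sd_bp: float = 0.3

    def __post_init__(self) -> None:
        if self.sizing_sd_bp < 0:
            raise ValueError("sizing_sd_bp must be >= 0")
        probs = dict(self.class_probs)
        if not probs:
            raise ValueError("class_probs must be nonempty")
        for k, p in probs.items():
            if k != CODING_HIT and not isinstance(k, (int, np.integer)):
                raise ValueError(f"class key must be int or {CODING_HIT!r}, got {k!r}")
            if p < 0:
                raise ValueError(f"probability for class {k!r} is negative")
        total = sum(probs.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"class probabilities must sum to 1, got {total}")


@dataclass(frozen=True)
class CloneRecord:
    """One sized 5-FOA-resistant clone.

    ``true_delta_units`` and ``coding_hit`` carry the planted ground truth
    and are only present for simulated clones; real capillary data has just
    the observed fragment length.
    """

    clone_id: str
    tract_id: str
    size_bp: float
    true_delta_units: int | None = None
    coding_hit: bool | None = None

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError("size_bp must be > 0")


# ---------------------------------------------------------------------------
# Luria–Delbrück distribution
# ---------------------------------------------------------------------------

# Cache of pmf prefixes keyed by m; the recursion is prefix-stable, so a
# longer vector simply extends a shorter one.
_PMF_CACHE: dict[float, np.ndarray] = {}
_PMF_CACHE_MAX_ENTRIES = 64


def ld_pmf(m: float, k_max: int) -> np.ndarray:
    """Probability mass p_0..p_k_max of the Luria--Delbrueck distribution.

    Uses the Ma--Sandri--Sarkar recursion

        p_0 = exp(-m),    p_k = (m/k) * sum_{j=0}^{k-1} p_j / (k - j + 1),

    which assumes mutations arise as a Poisson process proportional to
    population growth and mutant clones grow stochastically alongside the
    population (Lea--Coulson formulation).

    Parameters
    ----------
    m : expected number of mutation events per culture (>= 0).
    k_max : largest count to evaluate (>= 0).
    """
    if not math.isfinite(m) or m < 0:
        raise ValueError(f"m must be a finite nonnegative real, got {m}")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    k_max = int(k_max)
    cached = _PMF_CACHE.get(m)
    if cached is not None and len(cached) > k_max:
        return cached[: k_max + 1].copy()
    p = _extend_pmf(cached, m, k_max)
    if len(_PMF_CACHE) >= _PMF_CACHE_MAX_ENTRIES:
        _PMF_CACHE.clear()
    _PMF_CACHE[m] = p
    return p.copy()


def _extend_pmf(prefix: np.ndarray | None, m: float, k_max: int) -> np.ndarray:
    p = np.zeros(k_max + 1)
    if prefix is None:
        p[0] = math.exp(-m)
        start = 1
    else:
        p[: len(prefix)] = prefix
        start = len(prefix)
    # weights w[i] = 1/(i+1); p_k = (m/k) * dot(p[0:k], w[k-1], ..., w[0]+?)
    w = 1.0 / (np.arange(k_max + 1) + 1.0)
    for k in range(start, k_max + 1):
        p[k] = (m / k) * float(np.dot(p[:k], w[k:0:-1]))
    return p


def _as_rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


#: Largest support tabulated by the pmf recursion during sampling; rarer
#: draws are resolved exactly through the compound-Poisson tail sampler.
TAIL_SWITCH_K = 4096


def _compound_poisson_counts(m: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exact draws via the severity representation of the LD distribution.

    The Ma--Sandri--Sarkar recursion is the Panjer recursion of a compound
    Poisson law: K = sum of Poisson(m) clone sizes with P(S >= j) = 1/j.
    Clone sizes follow by inverse transform as floor(1/U).
    """
    counts = np.zeros(n, dtype=np.int64)
    n_clones = rng.poisson(m, size=n)
    total = int(n_clones.sum())
    if total:
        sizes = np.floor(1.0 / rng.random(total))
        sizes = np.minimum(sizes, 2.0**62).astype(np.int64)
        np.add.at(counts, np.repeat(np.arange(n), n_clones), sizes)
    return counts


def _sample_tail(
    m: float, k_cap: int, n: int, p_tail: float, rng: np.random.Generator
) -> np.ndarray:
    """Draws from the LD distribution conditioned on count > k_cap (rejection)."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    p_tail = max(p_tail, 1e-12)
    for _ in range(10_000):
        if filled == n:
            break
        batch_size = int((n - filled) / p_tail * 1.5) + 64
        batch = _compound_poisson_counts(m, min(batch_size, 2_000_000), rng)
        accepted = batch[batch > k_cap]
        take = min(len(accepted), n - filled)
        out[filled : filled + take] = accepted[:take]
        filled += take
    if filled < n:
        raise RuntimeError(f"tail rejection sampling failed to converge at m={m}")
    return out


def sample_mutant_counts(
    m: float, n_cultures: int, seed: Union[int, np.random.Generator]
) -> np.ndarray:
    """Draw per-culture mutant counts from the Luria--Delbrueck distribution.

    Inverse-CDF sampling of :func:`ld_pmf`, with the tabulated support
    doubled whenever a uniform draw falls beyond the accumulated mass.  The
    ~1/k^2 tail makes unbounded tabulation quadratic in the deepest draw,
    so beyond ``TAIL_SWITCH_K`` the rare tail draws are resolved exactly
    through the compound-Poisson severity representation of the same
    distribution (never truncated).
    """
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    if not math.isfinite(m) or m < 0:
        raise ValueError(f"m must be a finite nonnegative real, got {m}")
    rng = _as_rng(seed)
    if m == 0:
        return np.zeros(n_cultures, dtype=np.int64)
    u = rng.random(n_cultures)
    k_max = 64
    cum = np.cumsum(ld_pmf(m, k_max))
    u_top = u.max()
    while u_top > cum[-1] and k_max < TAIL_SWITCH_K:
        k_max = min(2 * k_max, TAIL_SWITCH_K)
        cum = np.cumsum(ld_pmf(m, k_max))
    counts = np.searchsorted(cum, u, side="left").astype(np.int64)
    in_tail = u > cum[-1]
    n_tail = int(in_tail.sum())
    if n_tail:
        counts[in_tail] = _sample_tail(m, k_max, n_tail, 1.0 - cum[-1], rng)
    return counts


# ---------------------------------------------------------------------------
# Forward simulators (independent oracles for the sampler)
# ---------------------------------------------------------------------------


def simulate_culture_forward(
    mu: float, n0: int, generations: int, seed: Union[int, np.random.Generator]
) -> tuple[int, int]:
    """Grow one culture by synchronous binary fission and return (nt, mutants).

    Each generation every cell divides; new mutants arise as
    Poisson(mu * nonmutant cells dividing) and existing mutant lineages
    double.  Total divisions over ``g`` generations equal n0*(2^g - 1) =
    nt - n0, so the expected number of mutation events matches
    mu*(nt - n0).  Note that synchronous division quantizes clone sizes to
    powers of two; see :func:`sample_forward_lea_coulson` for the
    event-level model whose count distribution matches :func:`ld_pmf`.
    """
    nt, mutants, _ = _forward_one(mu, n0, generations, _as_rng(seed))
    return nt, mutants


def _forward_one(
    mu: float, n0: int, generations: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    if not (0 <= mu < 1):
        raise ValueError("mu must be in [0, 1)")
    if n0 < 1 or generations < 1:
        raise ValueError("need n0 >= 1 and generations >= 1")
    nt = n0 << generations
    if nt >= 2**62:
        raise OverflowError(
            f"final population n0*2^g = {nt} exceeds representable counts"
        )
    nonmut = int(n0)
    mut = 0
    events = 0
    for _ in range(generations):
        k = int(rng.poisson(mu * nonmut)) if mu > 0 else 0
        k = min(k, 2 * nonmut)  # cannot mutate more daughters than exist
        events += k
        mut = 2 * mut + k
        nonmut = 2 * nonmut - k
    return nt, mut, events


def forward_culture_stats(
    mu: float,
    n0: int,
    generations: int,
    n_reps: int,
    seed: Union[int, np.random.Generator],
) -> tuple[int, np.ndarray, np.ndarray]:
    """Vectorized replicate runs of :func:`simulate_culture_forward`.

    Returns ``(nt, mutant_counts, event_counts)`` over ``n_reps`` cultures;
    used for distribution-level checks (mean event count, jackpot
    overdispersion) where looping one culture at a time would dominate
    runtime.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0 <= mu < 1):
        raise ValueError("mu must be in [0, 1)")
    if n0 < 1 or generations < 1:
        raise ValueError("need n0 >= 1 and generations >= 1")
    nt = n0 << generations
    if nt >= 2**62:
        raise OverflowError("final population exceeds representable counts")
    rng = _as_rng(seed)
    nonmut = np.full(n_reps, float(n0))
    mut = np.zeros(n_reps, dtype=np.int64)
    events = np.zeros(n_reps, dtype=np.int64)
    for _ in range(generations):
        k = rng.poisson(mu * nonmut) if mu > 0 else np.zeros(n_reps, dtype=np.int64)
        k = np.minimum(k, (2 * nonmut).astype(np.int64))
        events += k
        mut = 2 * mut + k
        nonmut = 2 * nonmut - k
    return nt, mut, events


def sample_forward_lea_coulson(
    mu: float,
    n0: float,
    nt: float,
    n_cultures: int,
    seed: Union[int, np.random.Generator],
) -> np.ndarray:
    """Event-level forward simulation of mutant counts (Lea--Coulson model).

    The population grows deterministically and exponentially from n0 to nt;
    mutation events arrive as a Poisson process with intensity proportional
    to growth (total mean m = mu*(nt - n0)); each mutant clone then grows as
    a stochastic Yule (pure-birth) process.  A clone born when the
    population has reached a fraction ``u`` of nt ends with Geometric(u)
    descendants.  This simulator never evaluates the Ma--Sandri--Sarkar
    recursion, so it serves as an independent distributional oracle for
    :func:`sample_mutant_counts`.
    """
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    if not (0 <= mu < 1) or not (1 <= n0 < nt):
        raise ValueError("need 0 <= mu < 1 and 1 <= n0 < nt")
    rng = _as_rng(seed)
    m = mu * (nt - n0)
    counts = np.zeros(n_cultures, dtype=np.int64)
    n_events = rng.poisson(m, size=n_cultures)
    total = int(n_events.sum())
    if total:
        # mutation times weighted by instantaneous growth => the final
        # population fraction at birth is uniform on (n0/nt, 1]
        u = rng.uniform(n0 / nt, 1.0, size=total)
        sizes = rng.geometric(u)
        np.add.at(counts, np.repeat(np.arange(n_cultures), n_events), sizes)
    return counts


# ---------------------------------------------------------------------------
# Assay-level simulation
# ---------------------------------------------------------------------------


def simulate_fluctuation_assay(
    params: LDParams,
    n_cultures: int,
    seed: Union[int, np.random.Generator],
    strain: str = "sim",
    tract_id: str = "sim",
    temperature_c: float = 23.0,
    genotype_tags: frozenset[str] = frozenset(),
) -> FluctuationExperiment:
    """Simulate one strain x tract fluctuation experiment.

    Per culture: the true mutant count is a Luria--Delbrueck draw with
    m = mu*(nt - n0); the selective plate shows Binomial(mutants,
    sel_plating_fraction) colonies and the nonselective titer plate shows
    Poisson(nt * ns_dilution_fraction) colonies.
    """
    if n_cultures < 1:
        raise ValueError("n_cultures must be >= 1")
    rng = _as_rng(seed)
    mutants = sample_mutant_counts(params.m, n_cultures, rng)
    sel = rng.binomial(mutants, params.sel_plating_fraction)
    ns = rng.poisson(params.nt * params.ns_dilution_fraction, size=n_cultures)
    cultures = [
        CultureObservation(
            culture_id=f"{strain}.{tract_id}.c{i + 1}",
            sel_colonies=int(sel[i]),
            sel_plating_fraction=params.sel_plating_fraction,
            ns_colonies=int(ns[i]),
            ns_dilution_fraction=params.ns_dilution_fraction,
        )
        for i in range(n_cultures)
    ]
    return FluctuationExperiment(
        strain=strain,
        tract_id=tract_id,
        cultures=cultures,
        genotype_tags=genotype_tags,
        temperature_c=temperature_c,
    )


def apply_reporter_selection(
    delta_units: int, coding_hit: bool, design: AssayDesign
) -> bool:
    """Would a clone with this tract change survive 5-FOA selection?

    * ``control_forward``: only coding hits inactivate the reporter.
    * ``plasmid_frameshift``: the tract is in frame with URA3, so a clone is
      selected iff the net length change is not a multiple of 3 bp (or the
      coding sequence itself is hit).
    * ``chromosomal_tnr``: the promoter tract blocks URA3 expression only
      once expanded by at least the threshold number of units (default +5
      from the 25-repeat reference, i.e. >29 total repeats); contractions
      are not selectable.
    """
    if coding_hit:
        return True
    if design.assay_type == "control_forward":
        return False
    if design.assay_type == "plasmid_frameshift":
        return delta_units != 0 and (delta_units * design.unit_bp) % 3 != 0
    # chromosomal_tnr
    return delta_units >= design.tnr_expansion_threshold_units


def simulate_resistant_clones(
    model: SpectrumModel,
    n_clones: int,
    seed: Union[int, np.random.Generator],
    tract_id: str | None = None,
    id_prefix: str = "clone",
) -> list[CloneRecord]:
    """Simulate sized 5-FOA-resistant clones under a spectrum model.

    Event classes are drawn from ``model.class_probs`` and filtered through
    :func:`apply_reporter_selection` until ``n_clones`` selectable clones
    accumulate (rejection sampling, so the emitted class proportions are the
    selection-conditional ones).  Fragment length is
    flank + unit*(ref_units + delta) + Normal(0, sizing_sd_bp).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    design = model.design
    classes = list(model.class_probs.keys())
    probs = np.array([model.class_probs[c] for c in classes], dtype=float)
    selectable = [
        c
        for c, p in zip(classes, probs)
        if p > 0
        and apply_reporter_selection(
            0 if c == CODING_HIT else int(c), c == CODING_HIT, design
        )
    ]
    if not selectable:
        raise UnselectableSpectrumError(
            "unselectable spectrum: no event class with positive probability "
            f"passes {design.assay_type} selection"
        )
    if tract_id is None:
        tract_id = f"{design.assay_type}_{design.unit_bp}x{design.ref_units}"
    rng = _as_rng(seed)
    probs = probs / probs.sum()
    records: list[CloneRecord] = []
    while len(records) < n_clones:
        batch = rng.choice(len(classes), size=max(n_clones, 64), p=probs)
        for idx in batch:
            c = classes[int(idx)]
            hit = c == CODING_HIT
            delta = 0 if hit else int(c)
            if not apply_reporter_selection(delta, hit, design):
                continue
            size = (
                design.flank_bp
                + design.unit_bp * (design.ref_units + delta)
                + (rng.normal(0.0, model.sizing_sd_bp) if model.sizing_sd_bp else 0.0)
            )
            records.append(
                CloneRecord(
                    clone_id=f"{id_prefix}{len(records) + 1:04d}",
                    tract_id=tract_id,
                    size_bp=size,
                    true_delta_units=delta,
                    coding_hit=hit,
                )
            )
            if len(records) == n_clones:
                break
    return records
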