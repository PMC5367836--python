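"""Synthetic flow-cytometry experiments with the structure the analysis assumes.

Each experimental group (strain x age x organ x population) carries a true
(a_G, a_M) "signature".  A sample is produced in three stages that mirror a
real acquisition:

1. forward-simulate the labelling protocol to get the expected
   six-compartment composition at sacrifice;
2. draw per-cell events: a DNA-content value (linear scale, 1 = 2N,
   2 = 4N, Gaussian 5% CV measurement noise around phase centres, S-phase
   cells uniform between 1 and 2) and an EdU intensity (two log-normal
   modes, labelled cells ~30x brighter); dead cells are appended as
   sub-G0/G1 apoptotic events and >4N events (macrophages that engulfed
   dying cells);
3. gate the events back to the dot-plot triplet plus dead counts, with
   aggregates (DNA in (2.2, 4]) discarded the way doublet exclusion would.

Dead cells never enter the kinetic fit — death is not part of the
compartment model — but the EdU+/dead ratio is reported as an expansion
performance index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    PopulationState,
    apply_hypotheses,
    rates_for_proliferation,
    steady_state,
)
from .protocol import Protocol, default_study_protocol
from .simulate import DotPlotSummary, SimConfig, endpoint_summary, simulate

__all__ = [
    "GroupDesign",
    "GateConfig",
    "GatingResult",
    "EventTable",
    "EmptyLiveError",
    "signature_presets",
    "expected_endpoint_state",
    "expected_triplet",
    "sample_triplet",
    "generate_events",
    "gate_events",
]

#: Event tables are plain DataFrames with columns
#: (event_id, dna_content, edu_intensity, true_class).
EventTable = pd.DataFrame

_LIVE_CLASSES = ("G", "S", "M", "Gp", "Sp", "Mp")

# log10 centres/SD of the two EdU intensity modes (arbitrary units)
_EDU_LOG10_UNLABELLED = 1.0
_EDU_LOG10_LABELLED = 2.5
_EDU_LOG10_SD = 0.2
_DNA_CV = 0.05
# cycling-cell acquisition window on the DNA axis (matches GateConfig defaults)
_LIVE_DNA_LO = 0.8
_LIVE_DNA_HI = 2.2


class EmptyLiveError(ValueError):
    """Gating found no live events to build a triplet from."""


@dataclass(frozen=True)
class GroupDesign:
    """One experimental group and its generating kinetics."""

    strain: str
    age_months: int
    organ: str
    population: str
    true_a_G: float
    true_a_M: float
    n_mice: int = 4
    n_events: int = 50_000
    dead_frac_apoptotic: float = 0.02
    dead_frac_engulfed: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_a_G <= 0 or self.true_a_M <= 0:
            raise ValueError("true rates must be > 0")
        for name in ("dead_frac_apoptotic", "dead_frac_engulfed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.3:
                raise ValueError(f"{name} must be in [0, 0.3]")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")

    @property
    def key(self) -> str:
        return f"{self.organ},{self.strain},{self.age_months}M,{self.population}"


@dataclass(frozen=True)
class GateConfig:
    """Gate boundaries on the DNA (linear) and EdU (log) axes.

    Live cells occupy DNA in [``dna_g1_lo``, ``dna_g2m_hi``]; events below
    ``dna_apoptotic_max`` are apoptotic (sub-G0/G1), above
    ``dna_engulfed_min`` (>4N) are macrophages that engulfed dying cells,
    and events in (``dna_g2m_hi``, ``dna_engulfed_min``] are discarded as
    aggregates.  An event is EdU-labelled if its intensity exceeds
    ``edu_threshold`` (midpoint of the two modes in log space).
    """

    dna_g1_lo: float = 0.8
    dna_g1_hi: float = 1.2
    dna_g2m_lo: float = 1.8
    dna_g2m_hi: float = 2.2
    dna_apoptotic_max: float = 0.7
    dna_engulfed_min: float = 4.0
    edu_threshold: float = 10 ** ((_EDU_LOG10_UNLABELLED + _EDU_LOG10_LABELLED) / 2)

    def __post_init__(self) -> None:
        order = (
            self.dna_apoptotic_max, self.dna_g1_lo, self.dna_g1_hi,
            self.dna_g2m_lo, self.dna_g2m_hi, self.dna_engulfed_min,
        )
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ValueError("gate boundaries must be strictly increasing")


@dataclass(frozen=True)
class GatingResult:
    """Gated triplet, dead-cell counts and the EdU+/dead expansion index."""

    summary: DotPlotSummary
    n_live: int
    n_apoptotic: int
    n_engulfed: int
    n_unlabelled_s: int
    n_discarded: int
    edu_dead_ratio: float  # NaN when no dead events were seen
    ratio_defined: bool

    @property
    def n_dead(self) -> int:
        return self.n_apoptotic + self.n_engulfed


def signature_presets() -> list[GroupDesign]:
    """Reference group designs spanning the observed kinetic range.

    True (a_G, a_M) pairs are chosen so the model proliferation rate matches
    the reported ballparks — about 32 %/day in whole thymus of young B6 mice
    down to 9 %/day in old FVB thymus, ~3 %/day in young spleen rising to
    ~13 %/day in old B6 spleen, up to 45 %/day for mature CD8 single-positive
    thymocytes and down to ~0.4 %/day for naive CD8 splenocytes — with G2/M
    durations from ~2 h (fast young-B6 thymocytes) to ~63 h (slow naive
    splenocytes).
    """
    spec = [
        # organ, strain, age, population, p (%/day), G2/M duration (h)
        ("thymus", "B6", 2, "total", 32.0, 2.0),
        ("thymus", "B6", 18, "total", 17.0, 4.0),
        ("thymus", "FVB", 2, "total", 17.0, 4.0),
        ("thymus", "FVB", 18, "total", 9.0, 6.0),
        ("thymus", "B6", 2, "TN", 20.0, 3.0),
        ("thymus", "FVB", 18, "DN1", 1.2, 12.0),
        ("thymus", "B6", 2, "DP CD3lo", 35.0, 2.0),
        ("thymus", "B6", 2, "DP CD3hi", 25.0, 3.0),
        ("thymus", "B6", 2, "CD4", 25.0, 3.0),
        ("thymus", "B6", 2, "CD8", 45.0, 2.0),
        ("thymus", "B6", 18, "CD8", 21.0, 4.0),
        ("thymus", "FVB", 2, "CD8", 3.0, 8.0),
        ("spleen", "B6", 2, "total", 3.0, 24.0),
        ("spleen", "FVB", 2, "total", 3.0, 24.0),
        ("spleen", "B6", 18, "total", 13.0, 12.0),
        ("spleen", "FVB", 18, "total", 7.0, 16.0),
        ("spleen", "B6", 2, "CD4 CD44lo", 0.8, 48.0),
        ("spleen", "B6", 2, "CD8 CD44lo", 0.44, 63.0),
        ("spleen", "B6", 2, "CD4 CD44hi", 7.0, 12.0),
        ("spleen", "B6", 2, "CD8 CD44hi", 6.5, 12.0),
        ("spleen", "B6", 2, "Treg", 21.0, 6.0),
        ("spleen", "FVB", 2, "Treg", 1.4, 24.0),
    ]
    designs = []
    for organ, strain, age, population, p_day, g2m_h in spec:
        a_G, a_M = rates_for_proliferation(p_day, g2m_h)
        designs.append(
            GroupDesign(
                strain=strain, age_months=age, organ=organ, population=population,
                true_a_G=a_G, true_a_M=a_M,
            )
        )
    return designs


def expected_endpoint_state(
    design: GroupDesign,
    protocol: Protocol | None = None,
    sim_config: SimConfig | None = None,
) -> PopulationState:
    """Noise-free six-compartment composition at sacrifice for a design."""
    if protocol is None:
        protocol = default_study_protocol()
    rates, labeling = apply_hypotheses(design.true_a_G, design.true_a_M)
    initial = steady_state(rates).initial_state()
    return simulate(rates, labeling, protocol, initial, sim_config).final_state


def expected_triplet(
    design: GroupDesign,
    protocol: Protocol | None = None,
    sim_config: SimConfig | None = None,
) -> DotPlotSummary:
    """Noise-free dot-plot triplet for a design (forward model composition)."""
    s = expected_endpoint_state(design, protocol, sim_config)
    return DotPlotSummary(pct_G=s.G, pct_M=s.M, pct_labelled=s.labelled)


def sample_triplet(
    expected: DotPlotSummary, n_events: int, seed: int | np.random.Generator = 0
) -> DotPlotSummary:
    """Multinomial counting noise on an expected triplet at a given event count."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = expected.as_array() / expected.total
    counts = rng.multinomial(n_events, probs)
    pct = 100.0 * counts / n_events
    return DotPlotSummary(*pct)


def _allocate_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation: integer counts matching proportions exactly."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def generate_events(
    design: GroupDesign,
    state: PopulationState,
    seed: int | np.random.Generator = 0,
) -> EventTable:
    """Draw an event table (DNA content x EdU intensity) for one sample.

    Live event counts follow the six-compartment proportions of ``state``
    exactly (largest-remainder rounding); measurement noise enters through
    the per-event DNA and EdU draws.  Dead events are appended at the
    design's apoptotic and engulfed fractions (relative to the live count).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    props = np.array(state.as_tuple(), dtype=float)
    if props.sum() <= 0:
        raise ValueError("state has no cells")
    props = props / props.sum()
    counts = _allocate_counts(props, design.n_events)

    dna_parts: list[np.ndarray] = []
    edu_parts: list[np.ndarray] = []
    classes: list[np.ndarray] = []

    def _edu(n: int, labelled: bool) -> np.ndarray:
        centre = _EDU_LOG10_LABELLED if labelled else _EDU_LOG10_UNLABELLED
        return 10.0 ** rng.normal(centre, _EDU_LOG10_SD, size=n)

    for cls, n in zip(_LIVE_CLASSES, counts):
        if n == 0:
            continue
        labelled = cls.endswith("p")
        phase = cls[0]
        if phase == "G":
            dna = rng.normal(1.0, _DNA_CV, size=n)
        elif phase == "M":
            dna = rng.normal(2.0, 2.0 * _DNA_CV, size=n)
        else:  # S phase: replicating DNA spans 2N..4N uniformly
            dna = rng.uniform(1.0, 2.0, size=n)
        # live cells stay inside the cycling acquisition window; jitter
        # saturates at the window edges rather than leaking into the
        # sub-G0/G1 or aggregate regions
        dna_parts.append(np.clip(dna, _LIVE_DNA_LO, _LIVE_DNA_HI))
        edu_parts.append(_edu(n, labelled))
        classes.append(np.full(n, cls, dtype=object))

    n_apop = round(design.dead_frac_apoptotic * design.n_events)
    if n_apop:
        dna_parts.append(rng.uniform(0.30, 0.65, size=n_apop))
        edu_parts.append(_edu(n_apop, labelled=False))
        classes.append(np.full(n_apop, "apoptotic", dtype=object))
    n_eng = round(design.dead_frac_engulfed * design.n_events)
    if n_eng:
        dna_parts.append(rng.uniform(4.3, 5.5, size=n_eng))
        edu_parts.append(_edu(n_eng, labelled=False))
        classes.append(np.full(n_eng, "engulfed", dtype=object))

    df = pd.DataFrame(
        {
            "dna_content": np.concatenate(dna_parts),
            "edu_intensity": np.concatenate(edu_parts),
            "true_class": np.concatenate(classes),
        }
    )
    df.insert(0, "event_id", np.arange(len(df)))
    return df


def plot_dotplot(events: EventTable, gates: GateConfig | None = None, ax=None):
    """EdU (log) vs DNA content (linear) scatter with gate lines — cosmetic."""
    import matplotlib.pyplot as plt

    if gates is None:
        gates = GateConfig()
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(events["dna_content"], events["edu_intensity"], s=2, alpha=0.3,
               linewidths=0)
    ax.set_yscale("log")
    for x in (gates.dna_g1_lo, gates.dna_g1_hi, gates.dna_g2m_lo, gates.dna_g2m_hi):
        ax.axvline(x, color="grey", lw=0.5)
    ax.axhline(gates.edu_threshold, color="red", lw=0.5)
    ax.set_xlabel("DNA content (linear, 1 = 2N)")
    ax.set_ylabel("EdU intensity (a.u.)")
    return ax


def gate_events(events: EventTable, gates: GateConfig | None = None) -> GatingResult:
    """Classify events into the dot-plot triplet, dead counts and the EdU+/dead ratio.

    Live events (DNA within the cycling window) are labelled when EdU
    intensity exceeds the threshold, regardless of DNA content; unlabelled
    events split by DNA into G0/G1 and G2/M (unlabelled mid-DNA events —
    genuine unlabelled S cells or gate spill-over — stay in the live
    denominator but outside the triplet).  The EdU+/dead ratio is flagged
    undefined when no dead events were observed.
    """
    if gates is None:
        gates = GateConfig()
    if len(events) == 0:
        raise EmptyLiveError("empty event table")
    dna = events["dna_content"].to_numpy(dtype=float)
    edu = events["edu_intensity"].to_numpy(dtype=float)

    apoptotic = dna < gates.dna_apoptotic_max
    engulfed = dna > gates.dna_engulfed_min
    live = (dna >= gates.dna_g1_lo) & (dna <= gates.dna_g2m_hi)
    n_discarded = int(len(events) - apoptotic.sum() - engulfed.sum() - live.sum())

    n_live = int(live.sum())
    if n_live == 0:
        raise EmptyLiveError("no live events inside the cycling DNA window")

    labelled = live & (edu > gates.edu_threshold)
    unl = live & ~labelled
    g = unl & (dna <= gates.dna_g1_hi)
    m = unl & (dna >= gates.dna_g2m_lo)
    n_unl_s = int(unl.sum() - g.sum() - m.sum())

    summary = DotPlotSummary(
        pct_G=100.0 * g.sum() / n_live,
        pct_M=100.0 * m.sum() / n_live,
        pct_labelled=100.0 * labelled.sum() / n_live,
    )
    n_dead = int(apoptotic.sum() + engulfed.sum())
    defined = n_dead > 0
    ratio = float(labelled.sum()) / n_dead if defined else float("nan")
    return GatingResult(
        summary=summary,
        n_live=n_live,
        n_apoptotic=int(apoptotic.sum()),
        n_engulfed=int(engulfed.sum()),
        n_unlabelled_s=n_unl_s,
        n_discarded=n_discarded,
        edu_dead_ratio=ratio,
        ratio_defined=defined,
    )
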