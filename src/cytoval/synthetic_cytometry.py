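"""Labeled synthetic listmode data: matrix mixtures and mast-cell spike-ins.

Each cell population is a multivariate log-normal cloud on the five
channels; ``location`` and ``spread`` are the mean and SD of log10
intensity per channel (channel order ``fsc, ssc, fl1_ige, fl2_cd117,
fl3_7aad``).  A matrix is a multinomial mixture of populations plus a dead
fraction (elevated 7-AAD) and a small background double-positive rate among
viable events, which is what drives a non-zero blank signal downstream.

Spike-ins target a nominal mast-cell percentage *among viable in-gate
events* — the same denominator the gating stage reports — so the recorded
:class:`SpikeInTruth` is directly comparable to the measured percentage.
"""

from __future__ import annotations

import importlib.resources
import tomllib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, ValidationError
from .io_formats import CHANNELS, EventTable, ExperimentDesign, concat_events

#: Labels that do not enter the viable in-gate denominator.
NON_VIABLE_LABELS: frozenset[str] = frozenset({"debris", "dead"})

#: Dead events re-use a live population's scatter/fluorescence but get their
#: 7-AAD channel overwritten from this log10 (location, spread).
_DEAD_FL3_LOC = 2.8
_DEAD_FL3_SPREAD = 0.2


@dataclass(frozen=True)
class PopulationSpec:
    """One population's mixture weight and log10-scale channel geometry."""

    name: str
    fraction: float
    location: tuple[float, ...]
    spread: tuple[float, ...]
    correlation: np.ndarray | None = None  # optional 5x5 log-scale correlation

    def __post_init__(self) -> None:
        if not (0 <= self.fraction <= 1):
            raise ConfigurationError(f"{self.name}: fraction must be in [0, 1]")
        loc = tuple(float(v) for v in self.location)
        spr = tuple(float(v) for v in self.spread)
        if len(loc) != len(CHANNELS) or len(spr) != len(CHANNELS):
            raise ConfigurationError(f"{self.name}: need {len(CHANNELS)} channel parameters")
        if any(s <= 0 for s in spr):
            raise ConfigurationError(f"{self.name}: spreads must be > 0")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "spread", spr)
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
                raise ConfigurationError(f"{self.name}: correlation must be symmetric 5x5")
            object.__setattr__(self, "correlation", corr)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` events as an (n, 5) array of linear intensities."""
        z = rng.standard_normal((n, len(CHANNELS)))
        if self.correlation is not None:
            z = z @ np.linalg.cholesky(self.correlation).T
        return 10.0 ** (np.asarray(self.location) + z * np.asarray(self.spread))


#: Default geometry of the spiked neoplastic mast-cell line: large, granular,
#: bright on both fluorescence markers, viable.
DEFAULT_MAST_SPEC = PopulationSpec(
    name="mast_cell",
    fraction=0.0,
    location=(2.90, 2.90, 3.20, 3.20, 0.40),
    spread=(0.15, 0.15, 0.20, 0.20, 0.25),
)


@dataclass(frozen=True)
class MatrixProfile:
    """Generative parameters for one matrix's cell suspension."""

    matrix: str
    populations: tuple[PopulationSpec, ...]
    dead_fraction: float
    background_dp_rate: float

    def __post_init__(self) -> None:
        pops = tuple(self.populations)
        total = sum(p.fraction for p in pops)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"population fractions sum to {total}, not 1")
        if not (0 <= self.dead_fraction < 1):
            raise ConfigurationError("dead_fraction must be in [0, 1)")
        if not (0 <= self.background_dp_rate <= 1e-3):
            raise ConfigurationError("background_dp_rate must be in [0, 0.001]")
        object.__setattr__(self, "populations", pops)

    @property
    def debris_fraction(self) -> float:
        return sum(p.fraction for p in self.populations if p.name == "debris")


def default_profile(matrix: str) -> MatrixProfile:
    """Load the packaged default profile for ``matrix`` (PB, BM or LN)."""
    res = importlib.resources.files("cytoval.profiles") / f"{matrix.lower()}.toml"
    try:
        raw = tomllib.loads(res.read_text())
    except FileNotFoundError as exc:
        raise ValidationError(f"no packaged profile for matrix {matrix!r}") from exc
    return MatrixProfile(
        matrix=raw["matrix"],
        populations=tuple(
            PopulationSpec(p["name"], p["fraction"],
                           tuple(p["location"]), tuple(p["spread"]))
            for p in raw["populations"]
        ),
        dead_fraction=raw["dead_fraction"],
        background_dp_rate=raw["background_dp_rate"],
    )


@dataclass(frozen=True)
class SpikeInTruth:
    """Ground truth recorded when mast cells are spiked into a matrix table."""

    nominal_fraction: float
    realized_count: int
    total_events: int

    def __post_init__(self) -> None:
        if not (0 <= self.realized_count <= self.total_events):
            raise ValidationError("realized_count must lie in [0, total_events]")


def viable_mask(events: EventTable) -> np.ndarray:
    """Boolean mask of events whose true label enters the measurement denominator."""
    if events.label is None:
        raise ValidationError("events must carry ground-truth labels")
    return ~np.isin(events.label.astype(str), list(NON_VIABLE_LABELS))


def simulate_matrix(profile: MatrixProfile, n_events: int,
                    seed: int | np.random.SeedSequence) -> EventTable:
    """Generate ``n_events`` labeled blank-matrix events.

    Population counts are multinomial around the profile fractions scaled by
    ``1 - dead_fraction``; dead events re-use a random live population's
    geometry with elevated 7-AAD; a binomial share of viable events gets
    mast-like fluorescence (label ``other``) at ``background_dp_rate``.
    No event is ever labeled ``mast_cell``.
    """
    if n_events < 1:
        raise ValidationError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    live = 1.0 - profile.dead_fraction
    probs = [p.fraction * live for p in profile.populations] + [profile.dead_fraction]
    counts = rng.multinomial(n_events, probs)

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for spec, k in zip(profile.populations, counts[:-1]):
        if k:
            blocks.append(spec.sample(int(k), rng))
            labels.append(np.full(int(k), spec.name, dtype=object))
    n_dead = int(counts[-1])
    if n_dead:
        templates = [p for p in profile.populations if p.name != "debris"] \
            or list(profile.populations)
        weights = np.array([p.fraction for p in templates])
        picks = rng.multinomial(n_dead, weights / weights.sum())
        dead_rows = [t.sample(int(k), rng) for t, k in zip(templates, picks) if k]
        dead = np.vstack(dead_rows) if dead_rows else np.empty((0, 5))
        dead[:, 4] = 10.0 ** (_DEAD_FL3_LOC
                              + _DEAD_FL3_SPREAD * rng.standard_normal(len(dead)))
        blocks.append(dead)
        labels.append(np.full(n_dead, "dead", dtype=object))

    mat = np.vstack(blocks) if blocks else np.empty((0, 5))
    lab = np.concatenate(labels) if labels else np.empty(0, dtype=object)
    events = EventTable(*(mat[:, i] for i in range(5)), label=lab)

    # background false double positives among viable events
    mask = viable_mask(events)
    n_live_events = int(mask.sum())
    if n_live_events and profile.background_dp_rate > 0:
        k = rng.binomial(n_live_events, profile.background_dp_rate)
        if k:
            idx = rng.choice(np.flatnonzero(mask), size=k, replace=False)
            fake = DEFAULT_MAST_SPEC.sample(k, rng)
            events.fl1_ige[idx] = fake[:, 2]
            events.fl2_cd117[idx] = fake[:, 3]
            events.label[idx] = "other"
    return events


def spike_mast_cells(matrix_events: EventTable, mast_spec: PopulationSpec,
                     nominal_fraction: float, seed: int | np.random.SeedSequence,
                     noise_cv: float = 0.0) -> tuple[EventTable, SpikeInTruth]:
    """Insert mast-cell events at ``nominal_fraction`` percent of viable events.

    With V viable matrix events the spike count is binomial with
    ``round(V / (1 - f/100))`` trials at success probability ``f/100``, so
    the expected mast share of the final viable denominator equals the
    nominal fraction.  ``noise_cv`` (percent) adds a per-call log-normal
    factor of mean 1 to that probability, emulating pipetting error.
    The returned table is shuffled.
    """
    if not (0 <= nominal_fraction < 100):
        raise ValidationError("nominal_fraction must be in [0, 100)")
    rng = np.random.default_rng(seed)
    n_mast = 0
    if nominal_fraction > 0:
        v = int(viable_mask(matrix_events).sum())
        p = nominal_fraction / 100.0
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p((noise_cv / 100.0) ** 2))
            p *= np.exp(rng.standard_normal() * sigma - sigma ** 2 / 2)
        n_trials = int(round(v / (1 - nominal_fraction / 100.0)))
        n_mast = int(rng.binomial(n_trials, min(p, 1.0)))
    if n_mast:
        mat = mast_spec.sample(n_mast, rng)
        spike = EventTable(*(mat[:, i] for i in range(5)),
                           label=np.full(n_mast, "mast_cell", dtype=object))
        out = concat_events([matrix_events, spike])
    else:
        out = matrix_events
    out = out.subset(rng.permutation(len(out)))
    return out, SpikeInTruth(nominal_fraction, n_mast, len(out))


def _child_seed(master: int, matrix: str, level_index: int,
                repeat_index: int) -> np.random.SeedSequence:
    """Deterministic independent stream per (matrix, level, repeat)."""
    matrix_code = {"PB": 1, "BM": 2, "LN": 3}[matrix]
    return np.random.SeedSequence((master, matrix_code, level_index, repeat_index))


def events_needed(design: ExperimentDesign, profile: MatrixProfile) -> int:
    """Raw draw size so the morphology gate holds >= ``design.min_events``."""
    in_gate = 1.0 - profile.debris_fraction * (1.0 - profile.dead_fraction)
    return int(np.ceil(design.min_events / in_gate * 1.02)) + 1000


def generate_dilution_series(
    design: ExperimentDesign,
    profile: MatrixProfile,
    mast_spec: PopulationSpec = DEFAULT_MAST_SPEC,
    noise_cv: float | Mapping[float, float] = 0.0,
) -> list[tuple[EventTable, SpikeInTruth]]:
    """Simulate the full validation series for one matrix.

    Returns one ``(EventTable, SpikeInTruth)`` per (level, repeat) pair in
    design order — levels descending, repeats inner — followed by
    ``n_blanks`` blank tables (nominal fraction 0).  All randomness derives
    from ``design.rng_seed``.  ``noise_cv`` may be a scalar percent or a
    mapping from nominal fraction to percent.
    """
    if design.matrix != profile.matrix:
        raise ConfigurationError(
            f"design matrix {design.matrix!r} != profile matrix {profile.matrix!r}")
    n_raw = events_needed(design, profile)
    out: list[tuple[EventTable, SpikeInTruth]] = []
    for li, frac in enumerate(design.nominal_fractions, start=1):
        cv = noise_cv.get(frac, 0.0) if isinstance(noise_cv, Mapping) else noise_cv
        for ri in range(design.repeats_per_level):
            ss = _child_seed(design.rng_seed, design.matrix, li, ri)
            sim_seed, spike_seed = ss.spawn(2)
            blank = simulate_matrix(profile, n_raw, sim_seed)
            out.append(spike_mast_cells(blank, mast_spec, frac, spike_seed, noise_cv=cv))
    for bi in range(design.n_blanks):
        ss = _child_seed(design.rng_seed, design.matrix, 0, bi)
        blank = simulate_matrix(profile, n_raw, ss)
        out.append((blank, SpikeInTruth(0.0, 0, len(blank))))
    return out
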