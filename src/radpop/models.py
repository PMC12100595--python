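"""Declarative two-deme demographic histories and their priors.

A :class:`DemographicModel` is an ordered list of events in backward time
(generations before present).  The module ships the nine named divergence
scenarios used throughout the analysis (M1 ... M4-one-mig): an ancestral
population splits into a Nearctic deme (index 0) and a Palearctic deme
(index 1), optionally with post-split bottlenecks in one or both demes and
with one of three migration regimes (none, continuous, or a single pulse in
each direction).

Conventions
-----------
* Effective sizes are **haploid** genome counts everywhere.
* Time is measured in generations before present; event times are >= 0.
* Migration is specified in backward-lineage terms: a continuous rate ``m``
  attached to deme *a* -> deme *b* is the per-lineage, per-generation rate
  at which a lineage currently in *a* jumps to *b* (equivalently, forward
  migration from *b* to *a*).  A pulse moves each lineage of the source
  deme with probability ``p`` at its time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DemographicEvent",
    "DemographicModel",
    "ModelParameters",
    "Prior",
    "CompiledSchedule",
    "build_model_library",
    "sample_parameters",
    "compile_backward",
    "default_priors",
    "reference_m4_parameters",
    "model_to_config",
    "model_from_config",
    "priors_to_config",
    "priors_from_config",
]

#: default mutation rate per site per generation (Lepidoptera direct estimate)
DEFAULT_MU = 2.9e-9
#: default generations per year used to convert times
DEFAULT_GENS_PER_YEAR = 4.0

_KINDS = ("deme_size_change", "divergence", "set_continuous_migration", "migration_pulse")

# stable application order for simultaneous events: migration-rate changes,
# then pulses, then divergences, then size changes
_KIND_PRIORITY = {
    "set_continuous_migration": 0,
    "migration_pulse": 1,
    "divergence": 2,
    "deme_size_change": 3,
}
# integer codes consumed by the simulation engine
KIND_CODES = {
    "deme_size_change": 0,
    "divergence": 1,
    "set_continuous_migration": 2,
    "migration_pulse": 3,
}


@dataclass
class DemographicEvent:
    """One backward-time event.

    ``time`` and numeric payload entries may be literal numbers or strings
    naming free parameters, resolved when the model is compiled.

    Payload keys by kind:

    - ``deme_size_change``: ``deme`` (int), ``size`` (haploid count)
    - ``divergence``: ``source`` (int), ``dest`` (int) — all lineages of
      ``source`` move into ``dest`` and ``source`` is retired
    - ``set_continuous_migration``: ``source``, ``dest`` (ints), ``rate``
    - ``migration_pulse``: ``source``, ``dest`` (ints), ``proportion``
    """

    kind: str
    time: float | str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")

    def parameter_refs(self) -> set[str]:
        refs = set()
        if isinstance(self.time, str):
            refs.add(self.time)
        for v in self.payload.values():
            if isinstance(v, str):
                refs.add(v)
        return refs


@dataclass
class DemographicModel:
    """A named demographic history over ``n_demes`` demes."""

    name: str
    n_demes: int
    events: list[DemographicEvent]

    @property
    def free_parameters(self) -> list[str]:
        refs: set[str] = set()
        for ev in self.events:
            refs |= ev.parameter_refs()
        return sorted(refs)

    @property
    def k(self) -> int:
        """Number of free parameters (the AIC dimension of the model)."""
        return len(self.free_parameters)


@dataclass
class ModelParameters:
    """A complete assignment of values to a model's free parameters.

    Sizes are haploid genome counts, times are generations before present.
    """

    values: dict
    mu: float = DEFAULT_MU
    gens_per_year: float = DEFAULT_GENS_PER_YEAR

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def resolve(self, x: float | str) -> float:
        if isinstance(x, str):
            try:
                return float(self.values[x])
            except KeyError:
                raise KeyError(f"parameter {x!r} has no assigned value") from None
        return float(x)

    def copy_with(self, **updates: float) -> "ModelParameters":
        vals = dict(self.values)
        vals.update(updates)
        return replace(self, values=vals)


@dataclass(frozen=True)
class Prior:
    """A univariate prior: ``uniform(lo, hi)`` or ``loguniform(lo, hi)``."""

    dist: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.dist not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        if not self.lo < self.hi:
            if self.lo == self.hi and self.dist == "uniform":
                pass  # degenerate point prior is allowed for pinning parameters
            else:
                raise ValueError("prior requires lo < hi")
        if self.dist == "loguniform" and self.lo <= 0:
            raise ValueError("loguniform prior requires lo > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "uniform":
            return float(rng.uniform(self.lo, self.hi))
        return float(math.exp(rng.uniform(math.log(self.lo), math.log(self.hi))))


class ModelError(ValueError):
    """Raised for structurally invalid demographic models."""


class ConfigurationError(ValueError):
    """Raised for incomplete prior / parameter configuration."""


# ---------------------------------------------------------------------------
# the nine scenarios
# ---------------------------------------------------------------------------

def _base_events(bottleneck_na: bool, bottleneck_pal: bool) -> list[DemographicEvent]:
    ev = [
        DemographicEvent("deme_size_change", 0.0, {"deme": 0, "size": "N_NA_cur"}),
        DemographicEvent("deme_size_change", 0.0, {"deme": 1, "size": "N_PAL_cur"}),
    ]
    if bottleneck_na:
        ev.append(DemographicEvent("deme_size_change", "T_bot_end", {"deme": 0, "size": "N_NA_bot"}))
    if bottleneck_pal:
        ev.append(DemographicEvent("deme_size_change", "T_bot_end", {"deme": 1, "size": "N_PAL_bot"}))
    ev.append(DemographicEvent("divergence", "T_split", {"source": 1, "dest": 0}))
    ev.append(DemographicEvent("deme_size_change", "T_split", {"deme": 0, "size": "N_anc"}))
    return ev


def _continuous_migration_events() -> list[DemographicEvent]:
    # backward rates from the present until the split (switched off by the
    # divergence, which retires deme 1)
    return [
        DemographicEvent("set_continuous_migration", 0.0,
                         {"source": 0, "dest": 1, "rate": "m_NA_PAL"}),
        DemographicEvent("set_continuous_migration", 0.0,
                         {"source": 1, "dest": 0, "rate": "m_PAL_NA"}),
    ]


def _pulse_events() -> list[DemographicEvent]:
    return [
        DemographicEvent("migration_pulse", "T_pulse_NA_PAL",
                         {"source": 0, "dest": 1, "proportion": "p_pulse_NA_PAL"}),
        DemographicEvent("migration_pulse", "T_pulse_PAL_NA",
                         {"source": 1, "dest": 0, "proportion": "p_pulse_PAL_NA"}),
    ]


def build_model_library() -> list[DemographicModel]:
    """Return the nine two-deme divergence scenarios.

    M1 family: no post-split bottleneck.  M2: Palearctic bottleneck only.
    M3: Nearctic bottleneck only.  M4: simultaneous bottlenecks in both
    demes.  ``-mig`` adds continuous migration from the split to the
    present; ``-one-mig`` adds one migration pulse in each direction.
    """
    lib = []
    for base, (bna, bpal) in (("M1", (False, False)), ("M2", (False, True)),
                              ("M3", (True, False)), ("M4", (True, True))):
        lib.append(DemographicModel(base, 2, _base_events(bna, bpal)))
        if base == "M1":
            lib.append(DemographicModel(
                "M1-mig", 2, _base_events(bna, bpal) + _continuous_migration_events()))
        lib.append(DemographicModel(
            f"{base}-one-mig", 2, _base_events(bna, bpal) + _pulse_events()))
    order = ["M1", "M1-mig", "M1-one-mig", "M2", "M2-one-mig",
             "M3", "M3-one-mig", "M4", "M4-one-mig"]
    lib.sort(key=lambda m: order.index(m.name))
    return lib


def get_model(name: str) -> DemographicModel:
    for m in build_model_library():
        if m.name == name:
            return m
    raise KeyError(name)


# ---------------------------------------------------------------------------
# priors & sampling
# ---------------------------------------------------------------------------

def default_priors() -> dict:
    """Default prior box for the nine scenarios.

    Size and time bounds bracket the demographic trajectories inferred for
    the study system (recent effective sizes of order 1e5-3e6 haploid
    genomes, recovery to several million, and a split well inside the last
    glacial cycle); migration rates and pulse proportions take the
    customary log-uniform priors.
    """
    return {
        "N_anc": Prior("uniform", 1e5, 5e6),
        "N_NA_bot": Prior("uniform", 1e5, 3e6),
        "N_PAL_bot": Prior("uniform", 1e5, 3e6),
        "N_NA_cur": Prior("uniform", 5e5, 8e6),
        "N_PAL_cur": Prior("uniform", 5e5, 8e6),
        "T_split": Prior("uniform", 1e4, 1e5),
        "T_bot_end": Prior("uniform", 1e3, 4e4),
        "m_NA_PAL": Prior("loguniform", 1e-10, 1e-4),
        "m_PAL_NA": Prior("loguniform", 1e-10, 1e-4),
        "T_pulse_NA_PAL": Prior("uniform", 1e2, 4e4),
        "T_pulse_PAL_NA": Prior("uniform", 1e2, 4e4),
        "p_pulse_NA_PAL": Prior("loguniform", 1e-6, 1.0),
        "p_pulse_PAL_NA": Prior("loguniform", 1e-6, 1.0),
    }


def reference_m4_parameters(t_bot_end: float = 24_000.0,
                            mu: float = DEFAULT_MU) -> ModelParameters:
    """Best-fit M4 history used as simulation ground truth.

    An ancestral population of ~1.4M haploid genomes splits ~47.6k
    generations ago; both demes bottleneck to ~8.5e5 and recover to their
    current sizes (5.15M Nearctic, 3.12M Palearctic).  The recovery time is
    not separately reported for the stepwise approximation, so the default
    places it near the midpoint of the post-split interval, which also
    reproduces the observed between-deme differentiation (see the methods
    note).
    """
    return ModelParameters({
        "N_anc": 1_395_858.0,
        "N_NA_bot": 868_595.0,
        "N_NA_cur": 5_154_456.0,
        "N_PAL_bot": 846_761.0,
        "N_PAL_cur": 3_124_738.0,
        "T_split": 47_622.0,
        "T_bot_end": float(t_bot_end),
    }, mu=mu)


def sample_parameters(model: DemographicModel, priors: dict, seed: int,
                      mu: float = DEFAULT_MU) -> ModelParameters:
    """Draw one parameter vector for ``model`` from ``priors``.

    Reproducible for a fixed seed.  Raises :class:`ConfigurationError` if a
    free parameter has no prior.
    """
    rng = np.random.default_rng(seed)
    vals = {}
    for name in model.free_parameters:
        if name not in priors:
            raise ConfigurationError(f"no prior declared for parameter {name!r}")
        vals[name] = priors[name].sample(rng)
    return ModelParameters(vals, mu=mu)


# ---------------------------------------------------------------------------
# compilation to a backward-time schedule
# ---------------------------------------------------------------------------

@dataclass
class CompiledSchedule:
    """Numeric backward-time schedule consumed by the coalescent engine.

    ``kinds`` uses :data:`KIND_CODES`; ``a``/``b`` are integer deme
    arguments and ``x`` the numeric payload (size, rate or proportion).
    Events are sorted ascending in time (ties broken by kind priority).
    """

    n_demes: int
    init_sizes: np.ndarray      # (n_demes,) haploid sizes at time 0
    times: np.ndarray           # (n_events,) float64, ascending
    kinds: np.ndarray           # (n_events,) int64 codes
    a: np.ndarray               # (n_events,) int64
    b: np.ndarray               # (n_events,) int64
    x: np.ndarray               # (n_events,) float64

    def normalized(self) -> list[tuple]:
        """Schedule with inert events removed, for structural comparison.

        Drops size changes that do not change the current size, zero-rate
        migration settings, zero-proportion pulses, and any event that
        refers to a deme already retired by a divergence.  Two histories
        that normalise identically define the same coalescent process.
        """
        sizes = self.init_sizes.astype(float).copy()
        alive = [True] * self.n_demes
        out = []
        for t, k, a, b, x in zip(self.times, self.kinds, self.a, self.b, self.x):
            k = int(k)
            a = int(a)
            b = int(b)
            if k == KIND_CODES["deme_size_change"]:
                if alive[a] and sizes[a] != x:
                    sizes[a] = x
                    out.append((float(t), "size", a, float(x)))
            elif k == KIND_CODES["divergence"]:
                alive[a] = False
                out.append((float(t), "divergence", a, b))
            elif k == KIND_CODES["set_continuous_migration"]:
                if alive[a] and alive[b] and x != 0.0:
                    out.append((float(t), "mig", a, b, float(x)))
            elif k == KIND_CODES["migration_pulse"]:
                if alive[a] and alive[b] and x != 0.0:
                    out.append((float(t), "pulse", a, b, float(x)))
        return out


def compile_backward(model: DemographicModel, params: ModelParameters) -> CompiledSchedule:
    """Resolve parameters and produce the sorted backward-time schedule.

    Validates the structural invariants: event times >= 0, sizes > 0,
    rates >= 0, pulse proportions in [0, 1], and exactly ``n_demes - 1``
    divergence events (exactly one for a two-deme model).
    """
    rows = []
    n_div = 0
    for ev in model.events:
        t = params.resolve(ev.time)
        if t < 0:
            raise ModelError(f"negative event time {t} in {model.name}")
        code = KIND_CODES[ev.kind]
        if ev.kind == "deme_size_change":
            size = params.resolve(ev.payload["size"])
            if size <= 0:
                raise ModelError(f"non-positive deme size {size}")
            rows.append((t, code, int(ev.payload["deme"]), 0, size))
        elif ev.kind == "divergence":
            n_div += 1
            src, dst = int(ev.payload["source"]), int(ev.payload["dest"])
            if src == dst:
                raise ModelError("divergence source and dest must differ")
            rows.append((t, code, src, dst, 0.0))
        elif ev.kind == "set_continuous_migration":
            rate = params.resolve(ev.payload["rate"])
            if rate < 0:
                raise ModelError(f"negative migration rate {rate}")
            rows.append((t, code, int(ev.payload["source"]), int(ev.payload["dest"]), rate))
        elif ev.kind == "migration_pulse":
            p = params.resolve(ev.payload["proportion"])
            if not 0.0 <= p <= 1.0:
                raise ModelError(f"pulse proportion {p} outside [0, 1]")
            rows.append((t, code, int(ev.payload["source"]), int(ev.payload["dest"]), p))
    if n_div != model.n_demes - 1:
        raise ModelError(
            f"model {model.name}: expected {model.n_demes - 1} divergence "
            f"event(s), found {n_div}")

    rows.sort(key=lambda r: (r[0], _KIND_PRIORITY[_KINDS[int(r[1])]]))

    init_sizes = np.full(model.n_demes, np.nan)
    kept = []
    for t, code, a, b, x in rows:
        if t == 0.0 and code == KIND_CODES["deme_size_change"]:
            init_sizes[a] = x
        kept.append((t, code, a, b, x))
    if np.isnan(init_sizes).any():
        raise ModelError(f"model {model.name}: every deme needs a size at time 0")

    arr = np.array(kept, dtype=float)
    return CompiledSchedule(
        n_demes=model.n_demes,
        init_sizes=init_sizes,
        times=arr[:, 0].astype(np.float64),
        kinds=arr[:, 1].astype(np.int64),
        a=arr[:, 2].astype(np.int64),
        b=arr[:, 3].astype(np.int64),
        x=arr[:, 4].astype(np.float64),
    )


# ---------------------------------------------------------------------------
# flat key-value configuration round trip
# ---------------------------------------------------------------------------

def _fmt(v) -> str:
    if isinstance(v, str):
        return v
    return repr(float(v))


def model_to_config(model: DemographicModel) -> str:
    lines = [f"model.name = {model.name}", f"model.n_demes = {model.n_demes}"]
    for i, ev in enumerate(model.events):
        parts = [f"kind={ev.kind}", f"time={_fmt(ev.time)}"]
        for key in sorted(ev.payload):
            parts.append(f"{key}={_fmt(ev.payload[key])}")
        lines.append(f"event.{i} = " + " ".join(parts))
    return "\n".join(lines) + "\n"


def _parse_scalar(s: str):
    try:
        return float(s)
    except ValueError:
        return s


def model_from_config(text: str) -> DemographicModel:
    name = None
    n_demes = None
    events: dict[int, DemographicEvent] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "model.name":
            name = value
        elif key == "model.n_demes":
            n_demes = int(float(value))
        elif key.startswith("event."):
            idx = int(key.split(".", 1)[1])
            fields = dict(tok.split("=", 1) for tok in value.split())
            kind = fields.pop("kind")
            time = _parse_scalar(fields.pop("time"))
            payload = {}
            for k, v in fields.items():
                payload[k] = int(float(v)) if k in ("deme", "source", "dest") \
                    else _parse_scalar(v)
            events[idx] = DemographicEvent(kind, time, payload)
    if name is None or n_demes is None:
        raise ConfigurationError("config missing model.name or model.n_demes")
    return DemographicModel(name, n_demes, [events[i] for i in sorted(events)])


def priors_to_config(priors: dict) -> str:
    lines = ["[priors]"]
    for name in sorted(priors):
        p = priors[name]
        lines.append(f"{name} = {p.dist} {repr(float(p.lo))} {repr(float(p.hi))}")
    return "\n".join(lines) + "\n"


def priors_from_config(text: str) -> dict:
    priors = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "[")):
            continue
        key, _, value = line.partition("=")
        dist, lo, hi = value.split()
        priors[key.strip()] = Prior(dist, float(lo), float(hi))
    return priors
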