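"""Mixed continuous/categorical design spaces for flow-reaction screening.

A reaction condition is a point in a space of continuous engineering
variables (equivalents, catalyst loading, temperature, concentration, flow
rate) plus categorical hardware choices (micromixer type).  For the
Gaussian-process surrogate the space is embedded in a numeric vector:
continuous variables are min-max scaled to the unit interval and each
k-way categorical variable becomes a k-dimensional one-hot block (choice
``i`` is the i-th standard basis vector).  Acquisition optimization runs
over the *relaxed* box [0, 1]^D in which one-hot blocks may be fractional;
relaxed vectors are mapped back to feasible conditions by nearest-vertex
rounding (argmax of the block) and snapping of continuous values to the
laboratory resolution grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "ValidationError",
    "DimensionError",
    "ContinuousParam",
    "CategoricalParam",
    "ParameterSpace",
    "Condition",
    "EncodedVector",
    "MixerSpec",
    "residence_time",
    "DEFAULT_MIXERS",
    "load_space_config",
    "dump_space_config",
]


class ValidationError(ValueError):
    """A condition, record or configuration violates the space's contract."""


class DimensionError(ValueError):
    """An encoded vector/matrix does not match the space's encoded dimension."""


@dataclass(frozen=True)
class ContinuousParam:
    """A bounded continuous variable in native laboratory units.

    ``precision`` is the lab resolution grid step used when proposals are
    snapped to values an experimentalist can actually set (e.g. 0.1 equiv,
    5 °C, 0.001 mL/min).
    """

    name: str
    low: float
    high: float
    units: str = ""
    precision: float = 1e-6

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(
                f"parameter {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )
        if not (self.precision > 0 and self.precision <= self.high - self.low):
            raise ValidationError(
                f"parameter {self.name!r}: precision must be in (0, high-low]"
            )

    def snap(self, value: float) -> float:
        """Round to the nearest multiple of ``precision``, clipped into bounds."""
        snapped = round(value / self.precision) * self.precision
        # kill representation noise like 2.3000000000000003
        snapped = float(np.round(snapped, 12))
        return min(max(snapped, self.low), self.high)


@dataclass(frozen=True)
class CategoricalParam:
    """An unordered choice variable; choice order fixes the one-hot layout."""

    name: str
    choices: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "choices", tuple(self.choices))
        if len(self.choices) < 2:
            raise ValidationError(f"parameter {self.name!r}: needs ≥2 choices")
        if len(set(self.choices)) != len(self.choices):
            raise ValidationError(f"parameter {self.name!r}: duplicate choices")


Param = Union[ContinuousParam, CategoricalParam]


@dataclass(frozen=True)
class Condition:
    """One fully specified reaction condition (native units / choice labels)."""

    assignments: Mapping[str, object]

    def __init__(self, assignments: Mapping[str, object]) -> None:
        object.__setattr__(self, "assignments", dict(assignments))

    def __getitem__(self, name: str) -> object:
        return self.assignments[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Condition):
            return NotImplemented
        return self.assignments == other.assignments

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.assignments.items())))

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self.assignments.items())
        return f"Condition({inner})"


@dataclass(frozen=True)
class EncodedVector:
    """Numeric embedding of a condition.

    ``relaxed`` is True when one-hot blocks may be fractional (vectors
    produced by the acquisition optimizer), False for exact embeddings of
    feasible conditions.
    """

    values: np.ndarray
    relaxed: bool = False

    def __init__(self, values: Iterable[float], relaxed: bool = False) -> None:
        object.__setattr__(self, "values", np.asarray(values, dtype=float))
        object.__setattr__(self, "relaxed", bool(relaxed))


class ParameterSpace:
    """Ordered mixed design space with a deterministic encoded layout.

    Encoded columns are: all continuous parameters in declaration order,
    then one one-hot block per categorical parameter in declaration order.
    """

    def __init__(self, params: Sequence[Param]):
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            raise ValidationError("parameter names must be unique")
        self.params: tuple[Param, ...] = tuple(params)
        self.continuous: tuple[ContinuousParam, ...] = tuple(
            p for p in params if isinstance(p, ContinuousParam)
        )
        self.categorical: tuple[CategoricalParam, ...] = tuple(
            p for p in params if isinstance(p, CategoricalParam)
        )
        self.encoded_dim: int = len(self.continuous) + sum(
            len(c.choices) for c in self.categorical
        )
        # column offsets of each one-hot block
        self._block_starts: list[int] = []
        off = len(self.continuous)
        for c in self.categorical:
            self._block_starts.append(off)
            off += len(c.choices)

    # ------------------------------------------------------------------ #
    # validation

    def validate(self, cond: Condition) -> None:
        seen = set(cond.assignments)
        expected = {p.name for p in self.params}
        if seen != expected:
            missing = expected - seen
            extra = seen - expected
            parts = []
            if missing:
                parts.append(f"missing parameter(s) {sorted(missing)}")
            if extra:
                parts.append(f"unknown parameter(s) {sorted(extra)}")
            raise ValidationError("; ".join(parts))
        for p in self.continuous:
            v = cond[p.name]
            if not isinstance(v, (int, float, np.integer, np.floating)) or not np.isfinite(v):
                raise ValidationError(f"parameter {p.name!r}: non-numeric value {v!r}")
            if not (p.low - 1e-12 <= float(v) <= p.high + 1e-12):
                raise ValidationError(
                    f"parameter {p.name!r}: value {v} outside [{p.low}, {p.high}] {p.units}"
                )
        for c in self.categorical:
            v = cond[c.name]
            if v not in c.choices:
                raise ValidationError(
                    f"parameter {c.name!r}: unknown label {v!r} (choices: {list(c.choices)})"
                )

    # ------------------------------------------------------------------ #
    # encode / decode

    def encode(self, cond: Condition) -> EncodedVector:
        """Embed a condition: unit-scaled continuous dims + one-hot blocks."""
        self.validate(cond)
        vec = np.zeros(self.encoded_dim)
        for i, p in enumerate(self.continuous):
            vec[i] = (float(cond[p.name]) - p.low) / (p.high - p.low)
        for c, start in zip(self.categorical, self._block_starts):
            vec[start + c.choices.index(cond[c.name])] = 1.0
        return EncodedVector(vec, relaxed=False)

    def encode_matrix(self, conds: Sequence[Condition]) -> np.ndarray:
        return np.array([self.encode(c).values for c in conds]).reshape(
            len(conds), self.encoded_dim
        )

    def decode(self, vec: Union[EncodedVector, np.ndarray]) -> Condition:
        """Map a (possibly relaxed) vector back to a feasible condition.

        Continuous dims are clipped to [0, 1] then unscaled; each one-hot
        block is rounded to its nearest vertex (largest component, ties to
        the lowest choice index).
        """
        values = vec.values if isinstance(vec, EncodedVector) else np.asarray(vec, float)
        if values.shape != (self.encoded_dim,):
            raise DimensionError(
                f"expected vector of length {self.encoded_dim}, got shape {values.shape}"
            )
        assignments: dict[str, object] = {}
        for i, p in enumerate(self.continuous):
            z = min(max(float(values[i]), 0.0), 1.0)
            assignments[p.name] = p.low + z * (p.high - p.low)
        for c, start in zip(self.categorical, self._block_starts):
            block = values[start : start + len(c.choices)]
            assignments[c.name] = c.choices[int(np.argmax(block))]
        return Condition(assignments)

    def snap_to_lab_grid(self, cond: Condition) -> Condition:
        """Round each continuous value to its precision grid; categorical kept."""
        self.validate(cond)
        assignments = dict(cond.assignments)
        for p in self.continuous:
            assignments[p.name] = p.snap(float(cond[p.name]))
        return Condition(assignments)

    # array-level helpers used by the acquisition optimizer ------------- #

    def snap_encoded(self, X: np.ndarray) -> np.ndarray:
        """Vectorized decode→snap→re-encode for a matrix of relaxed vectors.

        Rows of the result are exact embeddings of lab-grid conditions.
        """
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.encoded_dim:
            raise DimensionError(
                f"expected {self.encoded_dim} columns, got {X.shape[1]}"
            )
        out = np.zeros_like(X)
        for i, p in enumerate(self.continuous):
            z = np.clip(X[:, i], 0.0, 1.0)
            native = p.low + z * (p.high - p.low)
            native = np.round(np.round(native / p.precision) * p.precision, 12)
            native = np.clip(native, p.low, p.high)
            out[:, i] = (native - p.low) / (p.high - p.low)
        for c, start in zip(self.categorical, self._block_starts):
            block = X[:, start : start + len(c.choices)]
            idx = np.argmax(block, axis=1)
            out[np.arange(len(X)), start + idx] = 1.0
        return out

    def grid_conditions(self) -> list[Condition]:
        """Full enumeration of the lab grid (small spaces only)."""
        axes: list[list[object]] = []
        for p in self.continuous:
            n = int(round((p.high - p.low) / p.precision)) + 1
            axes.append([p.snap(p.low + k * p.precision) for k in range(n)])
        for c in self.categorical:
            axes.append(list(c.choices))
        names = [p.name for p in self.continuous] + [c.name for c in self.categorical]
        conds: list[Condition] = []
        idx = [0] * len(axes)
        while True:
            conds.append(Condition({n: axes[d][idx[d]] for d, n in enumerate(names)}))
            for d in range(len(axes) - 1, -1, -1):
                idx[d] += 1
                if idx[d] < len(axes[d]):
                    break
                idx[d] = 0
            else:
                break
        return conds


# ---------------------------------------------------------------------- #
# flow-engineering arithmetic


@dataclass(frozen=True)
class MixerSpec:
    """A micromixer/reactor with its internal volume."""

    name: str
    volume_mL: float

    def __post_init__(self) -> None:
        if not self.volume_mL > 0:
            raise ValidationError(f"mixer {self.name!r}: volume must be > 0 mL")


#: The three micromixers of the screening campaigns.  Volumes in mL.
DEFAULT_MIXERS: dict[str, MixerSpec] = {
    "comet_x": MixerSpec("comet_x", 2.4),
    "beta_type": MixerSpec("beta_type", 2.7),
    "t_shaped": MixerSpec("t_shaped", 1.6),
}

#: ASCII storage label → display label.
MIXER_DISPLAY = {"comet_x": "Comet X", "beta_type": "β-type", "t_shaped": "T-shaped"}


def residence_time(mixer: MixerSpec, per_stream_flow_mL_min: float) -> float:
    """Residence time (min) for a dual-syringe feed into ``mixer``.

    Two equal streams at ``per_stream_flow_mL_min`` combine, so the total
    volumetric flow through the reactor is twice the per-stream rate:
    t = V / (2 f).
    """
    if not per_stream_flow_mL_min > 0:
        raise ValidationError("flow rate must be > 0 mL/min")
    return mixer.volume_mL / (2.0 * per_stream_flow_mL_min)


# ---------------------------------------------------------------------- #
# config I/O


def load_space_config(source) -> tuple[ParameterSpace, dict[str, MixerSpec]]:
    """Read a YAML/JSON space declaration.

    Schema::

        parameters:
          - {name: temp_c, type: continuous, low: 20, high: 60, units: "°C", precision: 5}
          - {name: mixer, type: categorical, choices: [comet_x, beta_type, t_shaped]}
        mixers:
          - {name: comet_x, volume_mL: 2.4}
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ValidationError("space config must contain a 'parameters' list")
    params: list[Param] = []
    for entry in doc["parameters"]:
        kind = entry.get("type")
        if kind == "continuous":
            params.append(
                ContinuousParam(
                    name=entry["name"],
                    low=float(entry["low"]),
                    high=float(entry["high"]),
                    units=str(entry.get("units", "")),
                    precision=float(entry.get("precision", 1e-6)),
                )
            )
        elif kind == "categorical":
            params.append(CategoricalParam(entry["name"], entry["choices"]))
        else:
            raise ValidationError(
                f"parameter {entry.get('name')!r}: unknown type {kind!r}"
            )
    mixers = {
        m["name"]: MixerSpec(m["name"], float(m["volume_mL"]))
        for m in doc.get("mixers", [])
    }
    return ParameterSpace(params), mixers


def dump_space_config(space: ParameterSpace, mixers: Mapping[str, MixerSpec], path) -> None:
    doc: dict = {"parameters": []}
    for p in space.params:
        if isinstance(p, ContinuousParam):
            doc["parameters"].append(
                {
                    "name": p.name,
                    "type": "continuous",
                    "low": p.low,
                    "high": p.high,
                    "units": p.units,
                    "precision": p.precision,
                }
            )
        else:
            doc["parameters"].append(
                {"name": p.name, "type": "categorical", "choices": list(p.choices)}
            )
    doc["mixers"] = [
        {"name": m.name, "volume_mL": m.volume_mL} for m in mixers.values()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
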