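"""Named scenario presets for the three simulated cancer trajectories.

Five presets cover the study conditions: two local-growth variants
(dispersive / localised proposals from a single seed cell), a metastasis
run (primary-site block, decaying noise, rising growth rate) and two
apoptosis runs (connected clusters of 41 and 172 cancer cells under a
near-zero tolerance and a negative interaction parameter).  All presets
use a 128 x 128 lattice, rho = 0.2 and 100 trials.

Presets can be evaluated on a smaller lattice for quick experiments; seed
geometry (blob counts, block position/size) then scales with the lattice
so that the initial cancer *fraction* is preserved.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .dynamics import Schedule, SimParams
from .lattice import CellGrid, SeedSpec, make_grid, seed_grid

__all__ = ["ScenarioConfig", "make_scenario", "SCENARIO_NAMES", "DEFAULT_GRID_SHAPE"]

DEFAULT_GRID_SHAPE = (128, 128)

_PRESETS: dict[str, dict] = {
    "local_growth_dispersive": dict(
        params=dict(tol=0.60000, eps_in=2.77259, alpha=0.00610, noise=0.25),
        seed_spec=SeedSpec("single_center"),
    ),
    "local_growth_localised": dict(
        params=dict(tol=0.60000, eps_in=2.77259, alpha=0.00610, noise=0.00),
        seed_spec=SeedSpec("single_center"),
    ),
    "metastasis": dict(
        params=dict(
            tol=0.60000,
            eps_in=1.88001,
            alpha=Schedule(0.00061, 0.00610),
            noise=Schedule(0.30, 0.25),
        ),
        # the primary site: a small fully interior square patch
        seed_spec=SeedSpec("block", origin=(20, 20), extent=(12, 12)),
    ),
    "apoptosis_small": dict(
        params=dict(tol=0.00001, eps_in=-1.42670, alpha=0.00610, noise=0.25),
        seed_spec=SeedSpec("blob", count=41),
    ),
    "apoptosis_large": dict(
        params=dict(tol=0.00001, eps_in=-1.42670, alpha=0.00610, noise=0.25),
        seed_spec=SeedSpec("blob", count=172),
    ),
}

SCENARIO_NAMES = tuple(_PRESETS)


@dataclass
class ScenarioConfig:
    """A named, fully resolved simulation configuration."""

    name: str
    params: SimParams
    seed_spec: SeedSpec
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE

    def initial_grid(self, rng: np.random.Generator | None = None) -> CellGrid:
        grid = make_grid(*self.grid_shape)
        return seed_grid(grid, self.seed_spec, rng)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        p = asdict(self.params)
        for key in ("alpha", "noise"):
            v = getattr(self.params, key)
            if isinstance(v, Schedule):
                p[key] = f"{v.start}->{v.end}"
        return {
            "name": self.name,
            "grid_shape": list(self.grid_shape),
            "params": p,
            "seed_spec": {
                "pattern": self.seed_spec.pattern,
                "count": self.seed_spec.count,
                "origin": list(self.seed_spec.origin),
                "extent": list(self.seed_spec.extent),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        p = dict(d["params"])
        for key in ("alpha", "noise"):
            p[key] = _parse_schedule(p[key])
        ss = d["seed_spec"]
        return cls(
            name=d["name"],
            params=SimParams(**p),
            seed_spec=SeedSpec(
                pattern=ss["pattern"],
                count=int(ss["count"]),
                origin=tuple(ss["origin"]),
                extent=tuple(ss["extent"]),
            ),
            grid_shape=tuple(d["grid_shape"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))


def _parse_schedule(v) -> float | Schedule:
    """Parse a scalar or a ``start->end`` ramp string."""
    if isinstance(v, Schedule):
        return v
    if isinstance(v, str) and "->" in v:
        a, b = v.split("->")
        return Schedule(float(a), float(b))
    return float(v)


def _scale_seed_spec(spec: SeedSpec, grid_shape: tuple[int, int]) -> SeedSpec:
    """Rescale seed geometry to a non-default lattice, preserving the
    initial cancer fraction and relative placement."""
    if grid_shape == DEFAULT_GRID_SHAPE:
        return spec
    h, w = grid_shape
    h0, w0 = DEFAULT_GRID_SHAPE
    if spec.pattern == "blob":
        frac = spec.count / (h0 * w0)
        return replace(spec, count=max(1, round(frac * h * w)))
    if spec.pattern == "block":
        (r0, c0), (bh, bw) = spec.origin, spec.extent
        return replace(
            spec,
            origin=(round(r0 * h / h0), round(c0 * w / w0)),
            extent=(max(2, round(bh * h / h0)), max(2, round(bw * w / w0))),
        )
    return spec


def make_scenario(
    name: str,
    overrides: dict | None = None,
    *,
    grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
    trials: int = 100,
    seed: int | None = None,
) -> ScenarioConfig:
    """Build a named preset, optionally overriding individual parameters.

    ``overrides`` maps ``SimParams`` field names (plus ``grid_shape``) to
    new values; ramps can be given as ``"start->end"`` strings.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    overrides = dict(overrides or {})
    if "grid_shape" in overrides:
        grid_shape = tuple(overrides.pop("grid_shape"))
    if "trials" in overrides:
        trials = int(overrides.pop("trials"))
    if "seed" in overrides:
        seed = overrides.pop("seed")
    preset = _PRESETS[name]
    pkw = dict(preset["params"])
    pkw.update({"rho": 0.2, "trials": trials, "seed": seed})
    for key, val in overrides.items():
        if key in ("alpha", "noise"):
            val = _parse_schedule(val)
        pkw[key] = val
    params = SimParams(**pkw)
    seed_spec = _scale_seed_spec(preset["seed_spec"], grid_shape)
    return ScenarioConfig(name=name, params=params, seed_spec=seed_spec, grid_shape=grid_shape)
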