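"""Uniform ocean-warming scenario construction.

A total warming (default 4.0 degC between 2009 and 2100, the A1B
assumption) is interpolated linearly in time and added uniformly to the
temperature layer; every other layer is held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from habsuit.grid import GridError, LayerStack

DEFAULT_EPOCHS = (2030, 2050, 2080, 2100)


@dataclass
class ScenarioSpec:
    baseline_year: int = 2009
    horizon_year: int = 2100
    total_increase_c: float = 4.0
    epochs: tuple[int, ...] = DEFAULT_EPOCHS

    def __post_init__(self) -> None:
        if self.horizon_year <= self.baseline_year:
            raise ValueError("horizon_year must be after baseline_year")
        if self.total_increase_c < 0:
            raise ValueError("total_increase_c must be >= 0")
        for y in self.epochs:
            if not (self.baseline_year <= y <= self.horizon_year):
                raise ValueError(f"epoch {y} outside [{self.baseline_year}, {self.horizon_year}]")


def temperature_increment(spec: ScenarioSpec, year: int) -> float:
    """Linear warming increment for a given year, rounded to 2 decimals."""
    if not (spec.baseline_year <= year <= spec.horizon_year):
        raise ValueError(
            f"year {year} outside scenario range [{spec.baseline_year}, {spec.horizon_year}]"
        )
    frac = (year - spec.baseline_year) / (spec.horizon_year - spec.baseline_year)
    return round(spec.total_increase_c * frac, 2)


def apply_scenario(
    stack: LayerStack, delta_t: float, layer: str = "temperature"
) -> LayerStack:
    """Shift the temperature layer by ``delta_t`` at every valid cell.

    Only the temperature layer may be perturbed; depth, salinity, currents
    and landscape are held fixed by design, and requests to shift any other
    layer are rejected.
    """
    if layer != "temperature":
        raise ValueError(
            f"only the temperature layer may be perturbed in a warming scenario, "
            f"not {layer!r}; other variables are held fixed by design"
        )
    if "temperature" not in stack:
        raise GridError("stack has no 'temperature' layer to apply the scenario to")
    temp = stack["temperature"]
    warmed = temp.copy()
    warmed.values = warmed.values + delta_t
    warmed.values[warmed.nodata_mask] = temp.values[temp.nodata_mask]
    return stack.replace_layer(warmed)
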