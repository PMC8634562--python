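"""Measurement-level (level-1) residual variance structures.

Weight measurements are far more variable in adolescence than at birth,
so a constant residual variance is implausible over a 0-20 year span.
Two heteroscedastic structures are supported, both with all pairwise
covariances fixed at zero:

* ``segmented`` — the age range is cut into segments, each with its own
  residual variance (default: one cut at 2 years).
* ``age_linear`` — independent measurement-level random intercept and
  age slope, giving Var(e | age) = s0 + s1 * age**2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Level1VarianceSpec"]


@dataclass(frozen=True)
class Level1VarianceSpec:
    """Parametric form of the level-1 residual variance.

    ``cuts`` (segmented only) are strictly increasing interior age
    cut-points; ``k`` cuts give ``k + 1`` variance parameters.  The
    ``age_linear`` form always has two parameters ``(s0, s1)``.
    """

    kind: str = "segmented"
    cuts: tuple[float, ...] = (2.0,)

    def __post_init__(self) -> None:
        if self.kind not in ("segmented", "age_linear"):
            raise ValueError(f"unknown level-1 variance kind {self.kind!r}")
        if self.kind == "segmented":
            c = np.asarray(self.cuts, dtype=float)
            if c.size and np.any(np.diff(c) <= 0):
                raise ValueError("cuts must be strictly increasing")
            object.__setattr__(self, "cuts", tuple(float(x) for x in c))

    @property
    def n_params(self) -> int:
        return len(self.cuts) + 1 if self.kind == "segmented" else 2

    def param_names(self) -> list[str]:
        if self.kind == "age_linear":
            return ["sigma2_meas_intercept", "sigma2_meas_age"]
        edges = ["-inf", *[f"{c:g}" for c in self.cuts], "inf"]
        return [
            f"sigma2[{edges[i]},{edges[i + 1]}]" for i in range(len(edges) - 1)
        ]

    def segment_index(self, ages) -> np.ndarray:
        """Segment containing each age (segmented kind only)."""
        if self.kind != "segmented":
            raise ValueError("segment_index only applies to the segmented kind")
        return np.searchsorted(np.asarray(self.cuts), np.asarray(ages, float), side="left")

    def variance(self, ages, values) -> np.ndarray:
        """Residual variance at each age for parameter vector ``values``."""
        values = np.asarray(values, dtype=float)
        if values.size != self.n_params:
            raise ValueError(
                f"expected {self.n_params} level-1 parameters, got {values.size}"
            )
        if np.any(values < 0):
            raise ValueError("level-1 variances must be non-negative")
        a = np.asarray(ages, dtype=float)
        if self.kind == "segmented":
            return values[self.segment_index(a)]
        return values[0] + values[1] * a**2
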