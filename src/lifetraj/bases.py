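"""Nonlinear age bases for growth trajectories.

Two families are supported, matching common practice in growth-curve
modelling:

* **Fractional polynomials (FP)** of degree 1 or 2 over the power set
  {-2, -1, 0, 0.5, 1, 2, 3}, where power 0 denotes ``ln(t)`` and a
  repeated power (p, p) contributes ``t^p`` and ``t^p * ln(t)``.
* **Restricted cubic splines (RCS)** with 3-7 knots placed at Harrell's
  recommended age percentiles; the curve is constrained to be linear
  before the first and after the last knot.

Design matrices are returned as plain ``numpy`` arrays together with
column names, so they can be dropped into any regression design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FP_POWERS",
    "HARRELL_PERCENTILES",
    "BasisSpec",
    "fp_basis",
    "enumerate_fp_candidates",
    "rcs_knots",
    "rcs_basis",
    "basis_matrix",
]

#: Canonical fractional-polynomial power set.
FP_POWERS: tuple[float, ...] = (-2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0)

#: Harrell's recommended knot percentiles by number of knots.
HARRELL_PERCENTILES: dict[int, tuple[float, ...]] = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
    6: (5.0, 23.0, 41.0, 59.0, 77.0, 95.0),
    7: (2.5, 18.33, 34.17, 50.0, 65.83, 81.67, 97.5),
}


@dataclass(frozen=True)
class BasisSpec:
    """Description of one candidate trajectory basis.

    Parameters
    ----------
    family:
        ``"FP"`` or ``"RCS"``.
    powers:
        FP only: ordered multiset of length 1 or 2 drawn from
        :data:`FP_POWERS`; repeats allowed.
    knots:
        RCS only: strictly increasing knot ages in years (3-7 knots).
    age_shift:
        Constant added to age before FP power transforms.  Must be
        positive whenever the spec involves a logarithm or a
        non-positive power, because ages start at birth (0 years).
    """

    family: str
    powers: tuple[float, ...] | None = None
    knots: tuple[float, ...] | None = None
    age_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("FP", "RCS"):
            raise ValueError(f"unknown basis family {self.family!r}")
        if self.family == "FP":
            if self.powers is None or not 1 <= len(self.powers) <= 2:
                raise ValueError("FP basis needs 1 or 2 powers")
            bad = set(self.powers) - set(FP_POWERS)
            if bad:
                raise ValueError(f"powers {sorted(bad)} outside the FP power set")
            object.__setattr__(self, "powers", tuple(sorted(self.powers)))
            if self._needs_log() and self.age_shift <= 0:
                raise ValueError(
                    "age_shift must be > 0 for FP specs with non-positive or "
                    "repeated powers (log of age 0 is undefined)"
                )
        else:
            if self.knots is None or not 3 <= len(self.knots) <= 7:
                raise ValueError("RCS basis needs 3-7 knots")
            k = np.asarray(self.knots, dtype=float)
            if np.any(np.diff(k) <= 0):
                raise ValueError("RCS knots must be strictly increasing")
            object.__setattr__(self, "knots", tuple(float(x) for x in k))

    def _needs_log(self) -> bool:
        assert self.powers is not None
        return min(self.powers) <= 0 or len(set(self.powers)) < len(self.powers)

    @property
    def n_columns(self) -> int:
        if self.family == "FP":
            return len(self.powers)  # type: ignore[arg-type]
        return len(self.knots) - 1  # type: ignore[arg-type]

    def column_names(self) -> list[str]:
        if self.family == "FP":
            names = []
            prev: float | None = None
            for p in self.powers:  # type: ignore[union-attr]
                if prev is not None and p == prev:
                    names.append(f"{names[-1]}*log(t)")
                elif p == 0:
                    names.append("log(t)")
                else:
                    names.append(f"t^{p:g}")
                prev = p
            return names
        return ["age"] + [f"rcs{j}" for j in range(1, len(self.knots) - 1)]  # type: ignore[arg-type]

    def label(self) -> str:
        if self.family == "FP":
            return "FP(" + ",".join(f"{p:g}" for p in self.powers) + ")"  # type: ignore[union-attr]
        return f"RCS({len(self.knots)} knots)"  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        d: dict = {"family": self.family, "age_shift": self.age_shift}
        if self.powers is not None:
            d["powers"] = list(self.powers)
        if self.knots is not None:
            d["knots"] = list(self.knots)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            family=d["family"],
            powers=tuple(d["powers"]) if d.get("powers") else None,
            knots=tuple(d["knots"]) if d.get("knots") else None,
            age_shift=float(d.get("age_shift", 0.0)),
        )


def fp_basis(ages, spec: BasisSpec) -> np.ndarray:
    """Fractional-polynomial design columns for ``ages``.

    Power ``p`` maps ``t = age + age_shift`` to ``t**p`` (``ln t`` for
    ``p == 0``); a repeated power multiplies the previous column by
    ``ln t``.
    """
    if spec.family != "FP":
        raise ValueError("spec is not an FP basis")
    t = np.asarray(ages, dtype=float) + spec.age_shift
    if (spec._needs_log() or min(spec.powers) < 0) and np.any(t <= 0):  # type: ignore[arg-type]
        raise ValueError("non-positive transformed age with log/negative power")
    if np.any(t < 0):
        raise ValueError("negative transformed age")
    cols = []
    prev: float | None = None
    for p in spec.powers:  # type: ignore[union-attr]
        if prev is not None and p == prev:
            cols.append(cols[-1] * np.log(t))
        elif p == 0:
            cols.append(np.log(t))
        else:
            cols.append(t**p)
        prev = p
    return np.column_stack(cols)


def enumerate_fp_candidates(
    max_degree: int = 2,
    power_set: tuple[float, ...] = FP_POWERS,
    age_shift: float = 1.0,
) -> list[BasisSpec]:
    """All degree-1 and unordered degree-2 FP specs over ``power_set``.

    For the default 7 powers this yields 7 + C(7,2) + 7 = 35 candidates.
    Specs that involve a logarithm get ``age_shift`` (default 1 year) so
    they are well defined from birth; pure positive powers need none.
    """
    out: list[BasisSpec] = []
    for degree in range(1, max_degree + 1):
        for combo in itertools.combinations_with_replacement(power_set, degree):
            needs_log = min(combo) <= 0 or len(set(combo)) < len(combo)
            out.append(
                BasisSpec(
                    family="FP",
                    powers=combo,
                    age_shift=age_shift if needs_log else 0.0,
                )
            )
    return out


def rcs_knots(ages, n_knots: int) -> tuple[float, ...]:
    """Knot ages at Harrell's recommended percentiles of ``ages``."""
    if n_knots not in HARRELL_PERCENTILES:
        raise ValueError(f"n_knots must be in 3-7, got {n_knots}")
    a = np.asarray(ages, dtype=float)
    if np.unique(a).size < n_knots:
        raise ValueError("fewer distinct ages than requested knots")
    knots = np.percentile(a, HARRELL_PERCENTILES[n_knots])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            "percentile knots are tied (heavily discrete ages); "
            "supply explicit knots instead"
        )
    return tuple(float(k) for k in knots)


def rcs_basis(ages, knots) -> np.ndarray:
    """Restricted cubic spline design columns (Harrell's normalization).

    Column 1 is age itself; column ``j+1`` (j = 1..K-2) is::

        C_j(x) = [ (x-k_j)+^3
                   - (x-k_{K-1})+^3 * (k_K-k_j)/(k_K-k_{K-1})
                   + (x-k_K)+^3   * (k_{K-1}-k_j)/(k_K-k_{K-1}) ]
                 / (k_K - k_1)^2

    which is linear outside [k_1, k_K] and has continuous first and
    second derivatives everywhere.
    """
    x = np.asarray(ages, dtype=float)
    k = np.asarray(knots, dtype=float)
    if k.size < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(k) <= 0):
        raise ValueError("knots must be strictly increasing")
    K = k.size
    norm = (k[-1] - k[0]) ** 2
    denom = k[-1] - k[-2]
    cols = [x]
    for j in range(K - 2):
        cj = (
            np.clip(x - k[j], 0, None) ** 3
            - np.clip(x - k[-2], 0, None) ** 3 * (k[-1] - k[j]) / denom
            + np.clip(x - k[-1], 0, None) ** 3 * (k[-2] - k[j]) / denom
        ) / norm
        cols.append(cj)
    return np.column_stack(cols)


def basis_matrix(ages, spec: BasisSpec) -> np.ndarray:
    """Design columns for either family (dispatch helper)."""
    if spec.family == "FP":
        return fp_basis(ages, spec)
    return rcs_basis(ages, spec.knots)
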