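"""Parameter containers and reference fixtures.

The two-state ("open"/"closed") concerted binding model treats one cluster of
``n_sites`` equivalent porphyrin sites on the proteasome alpha-ring.  ``L`` is
the conformational equilibrium ratio [open]/[closed] at zero ligand, so the
closed state dominates the apo enzyme when ``L`` is small.  ``K_open`` and
``K_closed`` are the per-site association constants of the two conformations,
``k_on_open``/``k_on_closed`` the corresponding association rate constants and
``k_off`` the (single) dissociation rate constant of the cluster.

A permanently open particle (the alpha-3ΔN gate-deletion mutant) has no
closed-state branch; it is encoded by leaving the closed-state fields and
``L`` unset, which reduces the observed-rate law to simple bimolecular
binding, ``k_obs = k_on·x + k_off``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "TwoStateParams",
    "InhibitionParams",
    "DoseResponseParams",
    "ProgressPhases",
    "ToyComplexSpec",
    "ReferenceFixture",
    "get_fixture",
    "list_fixtures",
    "HUMAN_20S",
    "YEAST_20S",
    "ALPHA3DN",
]

_MECHANISMS = ("competitive", "uncompetitive", "mixed", "noncompetitive")


@dataclass(frozen=True)
class TwoStateParams:
    """Equilibrium and kinetic binding parameters of one site cluster.

    Units: association constants M^-1, association rate constants M^-1 s^-1,
    ``k_off`` s^-1, ``L`` dimensionless, ``n_sites`` sites per cluster.
    """

    k_on_open: float
    k_off: float
    K_open: Optional[float] = None
    K_closed: Optional[float] = None
    k_on_closed: Optional[float] = None
    L: Optional[float] = None
    n_sites: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("k_on_open", "k_off", "K_open", "K_closed", "k_on_closed", "L"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if self.n_sites is not None and self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")

    @property
    def is_bimolecular(self) -> bool:
        """True when no closed-state branch is defined (open-locked particle)."""
        return self.K_closed is None or self.k_on_closed is None or self.L is None

    def with_(self, **kw) -> "TwoStateParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class InhibitionParams:
    """Steady-state inhibition parameters (Vmax in rate units, Km/Ki in µM).

    ``alpha`` is the mixed-model interaction factor: the factor by which
    substrate binding changes inhibitor affinity.  Pure non-competitive
    inhibition is the mixed model with ``alpha = 1``.
    """

    mechanism: str
    vmax: float
    km: float
    ki: float
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mechanism not in _MECHANISMS:
            raise ValueError(
                f"unknown mechanism {self.mechanism!r}; expected one of {_MECHANISMS}"
            )
        for name in ("vmax", "km", "ki"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.mechanism in ("competitive", "uncompetitive") and self.alpha is not None:
            raise ValueError(f"alpha is undefined for the {self.mechanism} model")


@dataclass(frozen=True)
class DoseResponseParams:
    ic50: float  # µM
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not self.ic50 > 0:
            raise ValueError("ic50 must be > 0")
        if not self.hill > 0:
            raise ValueError("hill must be > 0")


@dataclass(frozen=True)
class ProgressPhases:
    """Phases of a stopped-flow progress curve: (signed amplitude AU, rate s^-1).

    Under the adopted sign convention a negative amplitude relaxes upward
    (hyperchromic phase) and a positive amplitude relaxes downward
    (hypochromic phase).
    """

    phases: tuple[tuple[float, float], ...]
    offset: float


@dataclass(frozen=True)
class ToyComplexSpec:
    """Planted ionic pairs (neg resname, pos resname, distance Å) plus decoys."""

    pairs: tuple[tuple[str, str, float], ...]
    decoys: int = 0


# ---------------------------------------------------------------------------
# Reference parameter sets (simulation ground truth)
# ---------------------------------------------------------------------------

HUMAN_20S = TwoStateParams(
    k_on_open=2.8e6,
    k_off=0.22,
    K_open=1.8e7,
    K_closed=7.0e3,
    k_on_closed=1.3e2,
    L=4.0e-6,
    n_sites=3,
    label="human",
)

YEAST_20S = TwoStateParams(
    k_on_open=7.0e6,
    k_off=1.06,
    K_open=1.8e7,
    K_closed=7.0e3,
    k_on_closed=1.3e2,
    L=4.0e-6,
    n_sites=3,
    label="yeast",
)

# Gate-deletion mutant, permanently open: simple bimolecular binding.
ALPHA3DN = TwoStateParams(
    k_on_open=2.5e6,
    k_off=7.0,
    K_open=3.6e5,
    label="alpha3dn",
)


@dataclass(frozen=True)
class ReferenceFixture:
    name: str
    kind: str  # kobs | inhibition | dose_response | progress | toy_complex | pseudo_ring
    params: object
    seed: int = 0


_FIXTURES: dict[str, ReferenceFixture] = {
    f.name: f
    for f in (
        ReferenceFixture("human-20s", "kobs", HUMAN_20S, seed=2),
        ReferenceFixture("yeast-20s", "kobs", YEAST_20S, seed=2),
        ReferenceFixture("alpha3dn", "kobs", ALPHA3DN, seed=2),
        ReferenceFixture(
            "chtl-dose-response", "dose_response", DoseResponseParams(ic50=2.0), seed=5
        ),
        ReferenceFixture(
            "suc-llvy-inhibition",
            "inhibition",
            InhibitionParams("noncompetitive", vmax=1.0, km=50.0, ki=2.0),
            seed=4,
        ),
        ReferenceFixture(
            "stopped-flow-two-phase",
            "progress",
            ProgressPhases(phases=((-0.05, 10.0), (0.03, 1.0)), offset=1.0),
            seed=3,
        ),
        ReferenceFixture(
            "toy-complex",
            "toy_complex",
            ToyComplexSpec(
                pairs=(("GLU", "LYS", 3.0), ("ASP", "ARG", 3.5), ("GLU", "ARG", 3.9)),
                decoys=6,
            ),
            seed=0,
        ),
        ReferenceFixture("pseudo-ring", "pseudo_ring", {"n_subunits": 7, "square_side": 17.0}, seed=0),
    )
}


def get_fixture(name: str) -> ReferenceFixture:
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)
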