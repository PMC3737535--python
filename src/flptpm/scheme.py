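"""Kinetic reaction scheme for Flp-FRT recombination observed by TPM.

The model is a small continuous-time state machine describing one tethered DNA
molecule carrying zero, one or two FRT sites.  Free molecules associate with
recombinase into either a *non-productive* complex (protein-bound sites that
never synapse stably and must dissociate first) or a *pre-synaptic* complex
(bound sites on the path to synapsis).  A pre-synaptic episode ends either in a
*wayward* synapse (type a: pairs but performs no chemistry, later falls back)
or an *active* synapse (type b: proceeds through strand cleavage to the
Holliday junction and recombinant product).  Chemistry is irreversible: once a
molecule reaches ``HOLLIDAY_OR_PRODUCT`` it never leaves before the SDS quench,
which strips all non-covalent protein-DNA contacts and reveals covalent
progress as a low (``POST_SDS_LOW``) or restored high (``POST_SDS_HIGH``) bead
excursion.

Association rates are second-order (M^-1 s^-1) and act pseudo-first-order at
the working recombinase concentration; all other rates are first-order (s^-1).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, asdict, replace

import yaml

__all__ = [
    "MoleculeState",
    "KineticScheme",
    "ExperimentProtocol",
    "default_scheme",
    "default_protocol",
    "pseudo_first_order",
    "to_second_order",
    "holliday_reachable",
]


class MoleculeState(enum.Enum):
    """Mechanistic state of one tethered molecule."""

    FREE = "FREE"
    NONPRODUCTIVE = "NONPRODUCTIVE"
    PRESYNAPTIC = "PRESYNAPTIC"
    SYNAPSED_WAYWARD = "SYNAPSED_WAYWARD"
    SYNAPSED_ACTIVE = "SYNAPSED_ACTIVE"
    HOLLIDAY_OR_PRODUCT = "HOLLIDAY_OR_PRODUCT"
    POST_SDS_HIGH = "POST_SDS_HIGH"
    POST_SDS_LOW = "POST_SDS_LOW"


VARIANTS = ("Flpe", "Y343F")
ORIENTATIONS = ("none", "single", "direct", "inverted")


@dataclass(frozen=True)
class KineticScheme:
    """Rate parameterization of the recombination state machine.

    Parameters
    ----------
    variant:
        Recombinase variant: ``"Flpe"`` (catalytically active) or ``"Y343F"``
        (cleavage nucleophile removed; no chemistry, ``k_r = 0``).
    orientation:
        FRT-site configuration of the substrate: ``"none"``, ``"single"``,
        ``"direct"`` (head-to-tail, excision) or ``"inverted"`` (head-to-head,
        inversion).
    k_f_np, k_f_ps:
        Second-order association constants (M^-1 s^-1) from ``FREE`` into the
        non-productive and pre-synaptic complexes.
    k_d_np:
        Decay of the non-productive complex back to ``FREE`` (s^-1).
    k_f_wayward, k_f_synaptic:
        Rates (s^-1) ending a pre-synaptic episode in a wayward (type a) or an
        active (type b) synapse.  Pre-synaptic dwells are an outcome-labelled
        mixture: the outcome is drawn first with probability ``p_type_b``,
        then the dwell is exponential with that outcome's own rate.  This is
        the parameterization under which type a and type b dwell pools have
        distinct single-exponential rates.
    k_d_wayward:
        Dissociation of the wayward synapse back to the pre-synaptic state.
    k_r:
        Headline recombination rate constant (s^-1): conversion of the active
        synapse into Holliday junction / product, as measured from the slow
        component of synapsed dwell decays.  Irreversible.
    p_type_b:
        Probability that a pre-synaptic episode is type b.
    k_first_chem:
        Rate of the first strand-exchange chemistry (active synapse ->
        covalent Holliday junction).  The observed endpoint fractions imply
        first-strand chemistry faster than ``k_r``; defaults to ``10 * k_r``
        and is deliberately configurable (see docs/methods.md).
    k_hj_resolve:
        Internal Holliday-junction resolution rate (HJ -> resolved product
        sub-state).  Junction isomerization/resolution is not slow; defaults
        to ``10 * k_r``.
    """

    variant: str
    orientation: str
    k_f_np: float = 0.0
    k_d_np: float = 0.0
    k_f_ps: float = 0.0
    k_f_wayward: float = 0.0
    k_f_synaptic: float = 0.0
    k_d_wayward: float = 0.0
    k_r: float = 0.0
    p_type_b: float = 0.0
    k_first_chem: float | None = None
    k_hj_resolve: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"unknown orientation {self.orientation!r}; expected one of {ORIENTATIONS}"
            )
        rates = {
            "k_f_np": self.k_f_np,
            "k_d_np": self.k_d_np,
            "k_f_ps": self.k_f_ps,
            "k_f_wayward": self.k_f_wayward,
            "k_f_synaptic": self.k_f_synaptic,
            "k_d_wayward": self.k_d_wayward,
            "k_r": self.k_r,
        }
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not 0.0 <= self.p_type_b <= 1.0:
            raise ValueError(f"p_type_b must be in [0, 1], got {self.p_type_b}")
        if self.variant == "Y343F" and self.k_r != 0.0:
            raise ValueError("Y343F carries no cleavage nucleophile: k_r must be 0")
        if self.k_first_chem is None:
            object.__setattr__(self, "k_first_chem", 10.0 * self.k_r)
        if self.k_hj_resolve is None:
            object.__setattr__(self, "k_hj_resolve", 10.0 * self.k_r)
        if self.k_first_chem < 0 or self.k_hj_resolve < 0:
            raise ValueError("k_first_chem and k_hj_resolve must be >= 0")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(**d)

    def to_yaml(self, stream=None) -> str | None:
        return yaml.safe_dump({"scheme": self.to_dict()}, stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, stream) -> "KineticScheme":
        if isinstance(stream, str) and "\n" not in stream:
            with open(stream) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(stream)
        return cls.from_dict(data["scheme"])

    def with_rates(self, **kwargs) -> "KineticScheme":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ExperimentProtocol:
    """Timing and concentration metadata for one TPM run.

    Recording starts at t = 0.  Recombinase is added at ``t_flp_add`` and SDS
    at ``t_sds`` (both in seconds on the recording clock); the first
    ``t_baseline`` seconds provide the protein-free baseline used by the
    substrate-length QC check, and recording continues for ``t_post_sds``
    seconds after the quench.  The default frame rate 29.85 Hz corresponds to
    200 frames in ~6.7 s.
    """

    flp_concentration: float = 2.0e-7  # M
    t_baseline: float = 100.0  # s of pre-addition trace used as baseline
    t_flp_add: float = 120.0  # s
    t_sds: float = 1920.0  # s (default: 30 min of reaction)
    frame_rate: float = 29.85  # Hz
    t_post_sds: float = 120.0  # s

    def __post_init__(self) -> None:
        if not (0 < self.t_baseline < self.t_flp_add <= self.t_sds):
            raise ValueError(
                "protocol requires 0 < t_baseline < t_flp_add <= t_sds; got "
                f"t_baseline={self.t_baseline}, t_flp_add={self.t_flp_add}, t_sds={self.t_sds}"
            )
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.flp_concentration < 0 or self.t_post_sds < 0:
            raise ValueError("flp_concentration and t_post_sds must be >= 0")

    @property
    def total_duration(self) -> float:
        """Total recorded time in seconds."""
        return self.t_sds + self.t_post_sds

    @property
    def reaction_window(self) -> float:
        """Seconds between recombinase addition and the SDS quench."""
        return self.t_sds - self.t_flp_add

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentProtocol":
        return cls(**d)

    def to_yaml(self, stream=None) -> str | None:
        return yaml.safe_dump({"protocol": self.to_dict()}, stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, stream) -> "ExperimentProtocol":
        if isinstance(stream, str) and "\n" not in stream:
            with open(stream) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(stream)
        return cls.from_dict(data["protocol"])


def default_protocol(**overrides) -> ExperimentProtocol:
    """The standard assay: 200 nM recombinase, 30 min reaction, SDS quench."""
    return ExperimentProtocol(**overrides)


# Fitted rate constants for each characterized variant/orientation.
# Association constants (k_f_np, k_f_ps) are second-order, M^-1 s^-1; all
# others s^-1.  p_type_b for direct sites is the branching ratio implied by
# the two pre-synaptic outcome rates; for inverted sites the two outcome
# rates were not separable and p_type_b is set from the amplitude split of
# the bi-exponential synapsed-dwell decay (0.15 slow / recombination).
_DEFAULTS: dict[tuple[str, str], dict] = {
    ("Flpe", "direct"): dict(
        k_f_np=1.8e5,
        k_d_np=4.0e-2,
        k_f_ps=6.0e4,
        k_f_wayward=1.7e-2,
        k_f_synaptic=4.9e-2,
        k_d_wayward=1.6e-2,
        k_r=1.7e-3,
        p_type_b=4.9 / (4.9 + 1.7),
    ),
    ("Flpe", "inverted"): dict(
        k_f_np=9.8e4,
        k_d_np=1.9e-2,
        k_f_ps=7.0e4,
        k_f_wayward=2.5e-2,
        k_f_synaptic=2.5e-2,
        k_d_wayward=1.7e-2,
        k_r=1.7e-3,
        p_type_b=0.15,
    ),
    ("Y343F", "direct"): dict(
        k_f_np=3.1e4,
        k_d_np=2.8e-2,
        k_f_ps=1.5e4,
        k_f_wayward=2.2e-2,
        k_f_synaptic=0.0,
        k_d_wayward=1.3e-2,
        k_r=0.0,
        p_type_b=0.0,
    ),
    # Substrates without a recombination-competent pair of sites: only
    # (transient) binding is possible.  The no-site control has no specific
    # interaction at all; the single-site substrate binds without synapsis.
    ("Flpe", "none"): dict(),
    ("Flpe", "single"): dict(k_f_np=1.8e5, k_d_np=4.0e-2),
    ("Y343F", "none"): dict(),
    ("Y343F", "single"): dict(k_f_np=3.1e4, k_d_np=2.8e-2),
}


def default_scheme(variant: str, orientation: str) -> KineticScheme:
    """Return the fitted kinetic scheme for a variant/orientation pair.

    Raises ``ValueError`` for combinations that were never characterized
    (e.g. Y343F with inverted sites).
    """
    try:
        params = _DEFAULTS[(variant, orientation)]
    except KeyError:
        raise ValueError(
            f"no default kinetic scheme for variant={variant!r}, "
            f"orientation={orientation!r}; characterized combinations are "
            f"{sorted(_DEFAULTS)}"
        ) from None
    return KineticScheme(variant=variant, orientation=orientation, **params)


def pseudo_first_order(k_second_order: float, concentration: float) -> float:
    """Observed first-order waiting rate (s^-1) at a fixed concentration."""
    if k_second_order < 0 or concentration < 0:
        raise ValueError("rate and concentration must be >= 0")
    return k_second_order * concentration


def to_second_order(k_obs: float, concentration: float) -> float:
    """Invert :func:`pseudo_first_order`: divide an observed rate by [Flp]."""
    if k_obs < 0 or concentration < 0:
        raise ValueError("rate and concentration must be >= 0")
    if concentration == 0:
        if k_obs == 0:
            return 0.0
        raise ValueError("cannot convert a nonzero observed rate at zero concentration")
    return k_obs / concentration


def holliday_reachable(scheme: KineticScheme) -> bool:
    """Whether HOLLIDAY_OR_PRODUCT is reachable from FREE under the scheme.

    Requires a path FREE -> PRESYNAPTIC -> SYNAPSED_ACTIVE -> chemistry, i.e.
    positive association, a positive type-b branch and ``k_r > 0``.
    """
    return (
        scheme.k_f_ps > 0
        and scheme.p_type_b > 0
        and scheme.k_f_synaptic > 0
        and scheme.k_r > 0
        and scheme.k_first_chem > 0
    )
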