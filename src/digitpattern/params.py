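"""Kinetic parameters of the GDF5/NOG/pSMAD reaction-diffusion network.

The model tracks six components on a 1D proximal-distal axis: the two mRNAs
(*GDF5*, *NOG*), the two free extracellular proteins (GDF5, NOG), the inert
NOG-GDF5 complex, and pSMAD activity as the nuclear readout of BMP signalling.
:class:`ModelParameters` collects every rate constant; units are μm, hours and
an arbitrary but consistent concentration unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import yaml

NogRegulation = Literal["repressed", "constant", "activated"]

#: Valid values for pSMAD regulation of NOG transcription. ``repressed`` is
#: the experimentally validated topology; the other two exist so that the
#: necessary-condition screen can interrogate them.
NOG_REGULATION_MODES = ("repressed", "constant", "activated")


@dataclass(frozen=True)
class ModelParameters:
    """All kinetic, binding, diffusion and regulatory constants.

    Attributes
    ----------
    D_G, D_N, D_C:
        Diffusion coefficients of free GDF5, free NOG and the NOG-GDF5
        complex (μm²/h).
    k_on, k_off:
        Complex association (1/(conc·h)) and dissociation (1/h) rates.
    alpha_G, alpha_N:
        Maximal transcription rates of *GDF5* and *NOG* mRNA (conc/h).
    beta_G, beta_N:
        Translation rates, mRNA → protein (1/h).
    delta_mG, delta_mN, delta_G, delta_N, delta_C:
        First-order removal rates of the two mRNAs, the two free proteins
        and the complex (1/h).
    K_S, h_S, S_max:
        Half-saturation, Hill exponent and ceiling of pSMAD activation by
        free GDF5.
    K_G, h_G:
        Half-repression constant and Hill exponent of *GDF5* transcription
        by pSMAD.
    K_N, h_N:
        Half-repression (or half-activation) constant and Hill exponent of
        *NOG* transcription by pSMAD.
    tau_S:
        pSMAD relaxation time (h); 0 encodes an instantaneous readout.
    nog_regulation:
        Sign of pSMAD's effect on *NOG* transcription.
    """

    D_G: float
    D_N: float
    D_C: float
    k_on: float
    k_off: float
    alpha_G: float
    alpha_N: float
    beta_G: float
    beta_N: float
    delta_mG: float
    delta_mN: float
    delta_G: float
    delta_N: float
    delta_C: float
    K_S: float
    h_S: float
    S_max: float
    K_G: float
    h_G: float
    K_N: float
    h_N: float
    tau_S: float = 0.0
    nog_regulation: str = "repressed"

    def __post_init__(self) -> None:
        positive = (
            "D_G", "D_N", "D_C", "k_on", "k_off", "alpha_G", "alpha_N",
            "beta_G", "beta_N", "delta_mG", "delta_mN", "delta_G", "delta_N",
            "delta_C", "K_S", "K_G", "K_N",
        )
        for name in positive:
            value = getattr(self, name)
            if not value >= 0.0:
                raise ValueError(f"parameter {name} must be >= 0, got {value!r}")
        # Hill constants must be strictly positive, exponents at least 1.
        for name in ("K_S", "K_G", "K_N"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"parameter {name} must be > 0")
        for name in ("h_S", "h_G", "h_N"):
            if not getattr(self, name) >= 1.0:
                raise ValueError(f"Hill exponent {name} must be >= 1")
        if self.S_max < 0.0:
            raise ValueError("S_max must be >= 0")
        if self.tau_S < 0.0:
            raise ValueError("tau_S must be >= 0")
        if self.nog_regulation not in NOG_REGULATION_MODES:
            raise ValueError(
                f"nog_regulation must be one of {NOG_REGULATION_MODES}, "
                f"got {self.nog_regulation!r}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def instantaneous_psmad(self) -> bool:
        """True when pSMAD is an algebraic readout (tau_S == 0)."""
        return self.tau_S == 0.0

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the named fields replaced."""
        unknown = set(changes) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParameters":
        names = set(cls.field_names())
        unknown = sorted(set(mapping) - names)
        if unknown:
            raise ValueError(f"unknown parameter key(s): {unknown}")
        required = {
            f.name
            for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING
        }
        missing = sorted(required - set(mapping))
        if missing:
            raise ValueError(f"missing parameter key(s): {missing}")
        return cls(**mapping)


def load_parameters(path) -> ModelParameters:
    """Load a :class:`ModelParameters` from a flat YAML/JSON key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} does not hold a key/value mapping")
    return ModelParameters.from_dict(data)


def save_parameters(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def reference_parameters(**overrides) -> ModelParameters:
    """The package's reference "wildtype" parameter set.

    Chosen so the predicted pattern wavelength is ~300 μm, the scale of
    newly initiated phalanges, with morphogen diffusivities and turnover
    rates in the physiological range. See ``docs/methods.md``.
    """
    ref = resources.files("digitpattern").joinpath("data/reference_params.yaml")
    with resources.as_file(ref) as path:
        params = load_parameters(path)
    if overrides:
        params = params.replace(**overrides)
    return params
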