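"""Ecosystem parameters and paradigm constraints.

All biological rate constants live in :class:`EcosystemParams`.  The printed
constants of the underlying formulation (maximum grazing rate 0.4 d⁻¹, grazing
preferences 0.3 / 0.1, the 15 °C diazotroph temperature cutoff, the Redfield
ratio and the 1.59 mg Chl a per mmol N conversion) are fixed defaults; every
other rate is a package calibration constant chosen so that the control
configuration equilibrates near the canonical global nitrogen-budget numbers
(fixation ≈ 70 Tg N yr⁻¹ balancing denitrification, excess-P inventory of a
few Pmol N in nitrogen equivalents).  Their provenance is "calibrated, not
from the source formulation" — see the config files and docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

PARADIGMS = ("CONTR", "GRAZ", "OLIGO", "DECAY")

#: default phosphate half-saturation of ordinary phytoplankton, mmol P m^-3
#: (nitrate half-saturation scaled down by the Redfield ratio)
_K_P_DEFAULT = 0.7 / 16.0


@dataclass
class EcosystemParams:
    """Rate constants, half-saturations, preferences and conversions.

    Units: rates d⁻¹, half-saturations mmol (N or P) m⁻³, preferences and
    fractions dimensionless, temperatures °C.
    """

    # growth
    J_O_max: float = 0.5          # max ordinary-phytoplankton growth rate, 1/d
    C_d: float = 0.33             # diazotroph growth handicap, (0, 1]
    k_N: float = 0.7              # NO3 half-saturation (ordinary), mmol N/m3
    k_P: float = _K_P_DEFAULT     # PO4 half-saturation (ordinary), mmol P/m3
    k_P_d: float = _K_P_DEFAULT   # PO4 half-saturation (diazotrophs), mmol P/m3
    T_min_diaz: float = 15.0      # diazotroph temperature cutoff, degC

    # grazing
    mu_max: float = 0.4           # max zooplankton grazing rate, 1/d
    theta_o: float = 0.3          # preference for ordinary phytoplankton
    theta_d: float = 0.3          # preference for diazotrophs (paradigm-set)
    theta_det: float = 0.1        # preference for detritus
    holling_saturation: bool = False  # optional saturating denominator
    k_graze: float = 0.5          # prey half-saturation of saturating form

    # stoichiometry / conversions
    r_NP: float = 16.0            # Redfield N:P molar ratio
    r_CN: float = 106.0 / 16.0    # C:N molar ratio
    chl_per_N: float = 1.59       # mg Chl a per mmol N

    # loss, recycling and export (calibrated)
    mort_phyto: float = 0.01      # linear phytoplankton mortality, 1/d
    assim_zoo: float = 0.3        # grazed fraction routed to zooplankton growth
    excret_zoo: float = 0.4       # grazed fraction excreted to nutrients
    mort_zoo: float = 0.004       # linear zooplankton loss, 1/d
    mort_zoo2: float = 0.0025    # quadratic zooplankton closure, (mmol N/m3)^-1 d^-1
    remin_surf: float = 0.07      # surface detritus remineralization, 1/d
    remin_deep: float = 0.01      # deep detritus remineralization, 1/d
    w_sink: float = 6.0           # detritus sinking velocity, m/d
    mort_deep: float = 0.03       # decay of living tracers mixed below the photic layer, 1/d

    # denitrification (deep boxes flagged as oxygen-minimum zones)
    f_denit: float = 0.38         # denitrified fraction of deep remineralized N
    k_denit: float = 0.5          # NO3 half-saturation of denitrification, mmol N/m3

    # horizontal exchange (relaxation towards the layer mean), 1/d
    kh_surf: float = 0.0
    kh_deep: float = 5.0e-8

    # numerics
    clip_epsilon: float = 1.0e-6  # negatives above -eps are clipped to zero

    @property
    def J_D_max(self) -> float:
        """Maximum diazotroph growth rate, ``C_d * J_O_max`` (d⁻¹)."""
        return self.C_d * self.J_O_max

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "J_O_max", "k_N", "k_P", "k_P_d", "mu_max", "r_NP", "r_CN",
            "chl_per_N", "mort_phyto", "remin_surf", "remin_deep", "w_sink",
            "mort_deep", "k_denit", "k_graze", "clip_epsilon",
        )
        for name in positive:
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if not 0.0 < self.C_d <= 1.0:
            raise ValueError("C_d must lie in (0, 1]")
        for name in ("theta_o", "theta_d", "theta_det"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"preference {name!r} must lie in [0, 1]")
        for name in ("assim_zoo", "excret_zoo", "f_denit"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"fraction {name!r} must lie in [0, 1]")
        if self.assim_zoo + self.excret_zoo > 1.0:
            raise ValueError("assim_zoo + excret_zoo must not exceed 1")
        for name in ("mort_zoo", "mort_zoo2", "kh_surf", "kh_deep"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be non-negative")

    def check_paradigm(self, paradigm: str) -> None:
        """Enforce the parameter relations that define a paradigm.

        CONTR/DECAY: equal grazing pressure and equal phosphate affinity.
        GRAZ: reduced grazing on diazotrophs, equal phosphate affinity.
        OLIGO: higher phosphate affinity for diazotrophs, equal grazing.
        """
        if paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {paradigm!r}")
        if paradigm in ("CONTR", "DECAY"):
            if self.theta_d != self.theta_o:
                raise ValueError(f"{paradigm} requires theta_d == theta_o")
            if self.k_P_d != self.k_P:
                raise ValueError(f"{paradigm} requires k_P_d == k_P")
        elif paradigm == "GRAZ":
            if not self.theta_d < self.theta_o:
                raise ValueError("GRAZ requires theta_d < theta_o")
            if self.k_P_d != self.k_P:
                raise ValueError("GRAZ requires k_P_d == k_P")
        elif paradigm == "OLIGO":
            if not self.k_P_d < self.k_P:
                raise ValueError("OLIGO requires k_P_d < k_P")
            if self.theta_d != self.theta_o:
                raise ValueError("OLIGO requires theta_d == theta_o")

    def replace(self, **kwargs) -> "EcosystemParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # ------------------------------------------------------------------
    # packed representation for the numerical kernel
    # ------------------------------------------------------------------
    _PACK_ORDER = (
        "J_O_max", "C_d", "k_N", "k_P", "k_P_d", "T_min_diaz",
        "mu_max", "theta_o", "theta_d", "theta_det", "k_graze",
        "r_NP", "mort_phyto", "assim_zoo", "excret_zoo", "mort_zoo",
        "mort_zoo2", "remin_surf", "remin_deep", "w_sink", "mort_deep",
        "f_denit", "k_denit", "kh_surf", "kh_deep", "clip_epsilon",
    )

    def pack(self, denit_enabled: bool = True) -> np.ndarray:
        """Flatten to the float64 vector consumed by the compiled kernel."""
        vec = [float(getattr(self, name)) for name in self._PACK_ORDER]
        vec.append(1.0 if self.holling_saturation else 0.0)
        vec.append(1.0 if denit_enabled else 0.0)
        return np.asarray(vec, dtype=np.float64)


#: paradigm-specific parameter presets applied on top of the defaults
PARADIGM_PRESETS = {
    "CONTR": {"theta_d": 0.3, "theta_o": 0.3, "k_P_d": _K_P_DEFAULT},
    "DECAY": {"theta_d": 0.3, "theta_o": 0.3, "k_P_d": _K_P_DEFAULT},
    "GRAZ": {"theta_d": 0.1, "theta_o": 0.3, "k_P_d": _K_P_DEFAULT},
    "OLIGO": {"theta_d": 0.3, "theta_o": 0.3, "k_P_d": 0.0122},
}


def default_params(paradigm: str = "CONTR", **overrides) -> EcosystemParams:
    """Parameter set for a paradigm, with validated overrides."""
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    kwargs = dict(PARADIGM_PRESETS[paradigm])
    kwargs.update(overrides)
    params = EcosystemParams(**kwargs)
    params.check_paradigm(paradigm)
    return params
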