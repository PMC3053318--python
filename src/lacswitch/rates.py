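"""Rate constants for the lac circuit kinetic model.

The model describes repression of the *lac* operon by the LacI dimer (R2),
relief of repression by a gratuitous inducer (TMG or IPTG), expression of the
permease LacY, and — in the positive-feedback variant — active import of
inducer by LacY.  All second-order constants are stored as molar association
rates (M^-1 s^-1) together with the reaction volume, so the stochastic
propensity conversion ``k / (N_A * V)`` is always reproducible.

Statistical-factor convention: a repressor dimer carries two identical,
independent inducer-binding sites.  The stored first-association rate is twice
the per-site rate and the stored second-dissociation rate is twice the
per-site dissociation rate, which is why the tabulated on-rates come in exact
2:1 pairs and the off-rates in exact 1:2 pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import yaml

#: Avogadro's number (mol^-1), CODATA exact value.
AVOGADRO = 6.02214076e23


class ConfigurationError(ValueError):
    """Raised when a rate set or network request is internally inconsistent."""


@dataclass
class LacRates:
    """Complete parameter set of the lac switch model.

    Units: second-order rates in M^-1 s^-1, first-order rates in s^-1,
    volume in liters, doubling time in seconds.
    """

    # repressor-operator binding / unbinding
    k_rb: float = 2.43e6        # R2 + O association
    k_ro_off: float = 6.30e-4   # RO dissociation
    k_iro_off: float = 6.30e-4  # IRO dissociation
    k_i2ro_off: float = 3.15e-1  # I2RO dissociation ("knock-off")

    # expression
    k_ts: float = 1.26e-1       # transcription initiation from free operator
    k_tl: float = 4.44e-2       # translation per mRNA
    k_mdeg: float = 1.11e-2     # mRNA degradation (RNase E)
    k_pdeg: float = 2.10e-4     # protein loss by dilution

    # inducer <-> free repressor (first/second site; factor-2 convention)
    inducer_on_free_1: float = 2.27e4
    inducer_on_free_2: float = 1.14e4
    inducer_off_free_1: float = 2.0e-1
    inducer_off_free_2: float = 4.0e-1

    # inducer <-> repressor-operator complex
    inducer_on_cplx_1: float = 6.67e2
    inducer_on_cplx_2: float = 3.33e2
    inducer_off_cplx_1: float = 1.0
    inducer_off_cplx_2: float = 2.0

    # inducer transport
    k_diff_in: float = 2.33e-3   # passive membrane diffusion (in)
    k_diff_out: float = 2.33e-3  # passive membrane diffusion (out)
    k_y_on: float = 3.03e4       # LacY + inducer association
    k_y_off: float = 1.2e-1      # LacY-inducer dissociation
    k_cat: float = 1.2e1         # transport turnover

    # structural / derived-input parameters
    C: float = 0.5               # IR2-operator binding proportionality
    C2: float = 0.01             # I2R2-operator binding proportionality
    R_tot: int = 10              # repressor dimers per cell (held constant)
    V: float = 8.0e-16           # reaction volume (L); intra == extra volume
    T_double: float = 55.0 * 60.0  # cell doubling time (s)
    inducer: str = "TMG"

    # ------------------------------------------------------------------ #
    # derived quantities
    # ------------------------------------------------------------------ #
    @property
    def k_irb(self) -> float:
        """IR2-operator association rate, C * k_rb (M^-1 s^-1)."""
        return self.C * self.k_rb

    @property
    def k_i2rb(self) -> float:
        """I2R2-operator association rate, C2 * k_rb (M^-1 s^-1)."""
        return self.C2 * self.k_rb

    @property
    def tau_p(self) -> float:
        """Mean protein lifetime 1/k_pdeg (s)."""
        return 1.0 / self.k_pdeg

    @property
    def tau_m(self) -> float:
        """Mean mRNA lifetime 1/k_mdeg (s)."""
        return 1.0 / self.k_mdeg

    @property
    def proteins_per_mrna(self) -> float:
        """Mean proteins translated over one mRNA lifetime, k_tl/k_mdeg."""
        return self.k_tl / self.k_mdeg

    @property
    def K_ID(self) -> float:
        """Per-site inducer dissociation constant of free repressor (M)."""
        return self.inducer_off_free_1 / (self.inducer_on_free_1 / 2.0)

    @property
    def K_MC(self) -> float:
        """Per-site inducer dissociation constant of the R-O complex (M)."""
        return self.inducer_off_cplx_1 / (self.inducer_on_cplx_1 / 2.0)

    @property
    def K_M(self) -> float:
        """Michaelis constant of LacY transport, (k_y_off + k_cat)/k_y_on (M)."""
        return (self.k_y_off + self.k_cat) / self.k_y_on

    def bimolecular(self, k_molar: float) -> float:
        """Convert a molar rate to a per-molecule-pair propensity constant."""
        return k_molar / (AVOGADRO * self.V)

    def concentration_to_count(self, conc: float) -> int:
        """Molecule count corresponding to a molar concentration in volume V."""
        return int(round(conc * AVOGADRO * self.V))

    # ------------------------------------------------------------------ #
    # validation
    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        """Check the structural invariants of the rate set.

        Raises :class:`ConfigurationError` on the first violation.
        """
        rate_fields = [
            "k_rb", "k_ro_off", "k_iro_off", "k_i2ro_off", "k_ts", "k_tl",
            "k_mdeg", "k_pdeg", "inducer_on_free_1", "inducer_on_free_2",
            "inducer_off_free_1", "inducer_off_free_2", "inducer_on_cplx_1",
            "inducer_on_cplx_2", "inducer_off_cplx_1", "inducer_off_cplx_2",
            "k_diff_in", "k_diff_out", "k_y_on", "k_y_off", "k_cat",
        ]
        for name in rate_fields:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"rate {name} must be > 0")
        if self.V <= 0:
            raise ConfigurationError("volume V must be > 0")
        if self.R_tot < 1:
            raise ConfigurationError("R_tot must be >= 1")

        def ratio_ok(x, y, tol):
            return abs(x / y - 1.0) <= tol

        if not ratio_ok(self.inducer_on_free_1, 2 * self.inducer_on_free_2, 0.005):
            raise ConfigurationError(
                "free-repressor on-rates violate the two-site statistical "
                "factor (on_1 must be 2 * on_2)")
        if not ratio_ok(self.inducer_off_free_2, 2 * self.inducer_off_free_1, 0.005):
            raise ConfigurationError(
                "free-repressor off-rates violate the two-site statistical "
                "factor (off_2 must be 2 * off_1)")
        if not ratio_ok(self.inducer_on_cplx_1, 2 * self.inducer_on_cplx_2, 0.005):
            raise ConfigurationError(
                "complex on-rates violate the two-site statistical factor")
        if not ratio_ok(self.inducer_off_cplx_2, 2 * self.inducer_off_cplx_1, 0.005):
            raise ConfigurationError(
                "complex off-rates violate the two-site statistical factor")
        if not ratio_ok(self.k_y_on, (self.k_y_off + self.k_cat) / self.K_M, 0.005):
            # K_M is itself derived from these rates, so this can only fire
            # after manual field edits; kept as a tripwire.
            raise ConfigurationError("transport rates inconsistent with K_M")
        if not ratio_ok(self.k_pdeg, math.log(2.0) / self.T_double, 0.01):
            raise ConfigurationError(
                "protein dilution rate inconsistent with doubling time "
                "(k_pdeg must equal ln2 / T_double within 1%)")

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            if isinstance(val, str):
                out[key] = val
            elif key == "R_tot":
                out[key] = int(val)
            else:
                out[key] = float(val)  # plain floats (YAML-safe)
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "LacRates":
        rates = cls(**data)
        rates.validate()
        return rates

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LacRates":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def defaults(cls, inducer: str = "TMG") -> "LacRates":
        """Tabulated defaults for either gratuitous inducer."""
        with resources.files("lacswitch.data").joinpath("rates.yaml").open() as fh:
            table = yaml.safe_load(fh)
        if inducer not in table:
            raise ConfigurationError(
                f"unknown inducer {inducer!r}; expected one of {sorted(table)}")
        return cls.from_dict(table[inducer])


def transport_rate_consistency(rates: LacRates, tol: float = 0.005) -> bool:
    """Check the LacY transport convention.

    True iff the dissociation rate is 1% of the turnover rate and the
    association rate satisfies k_y_on = (k_y_off + k_cat) / K_M within
    ``tol`` relative, using the transport Michaelis constant implied by a
    default-constructed rate set of the same inducer (400 uM for TMG).
    """
    reference_km = LacRates(inducer=rates.inducer).K_M
    if abs(rates.k_y_off / (0.01 * rates.k_cat) - 1.0) > tol:
        return False
    expected = (rates.k_y_off + rates.k_cat) / reference_km
    return abs(rates.k_y_on / expected - 1.0) <= tol


def repressor_search_time(rates: LacRates) -> float:
    """Mean time (s) for a single repressor dimer to find the free operator.

    Diffusion-limited association at k_rb in volume V gives
    ``N_A * V / k_rb``; with Table-derived defaults this is ~200 s.
    """
    return 1.0 / rates.bimolecular(rates.k_rb)
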