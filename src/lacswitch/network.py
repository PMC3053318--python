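"""Reaction network construction for the lac switch.

Two model variants are supported:

``PFB``
    The full positive-feedback circuit.  Extracellular inducer (clamped at a
    constant count, mimicking an infinite reservoir) enters the cell by
    passive membrane diffusion and by LacY-mediated transport, expanded into
    explicit bind / unbind / catalysis elementary steps.

``NPF``
    The circuit with the feedback loop severed (experimentally: the permease
    gene replaced by a transport-dead membrane protein).  Transport and
    passive diffusion are removed and the intracellular inducer count is
    clamped, so the operator subsystem sees a fixed inducer concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import AVOGADRO, ConfigurationError, LacRates

#: canonical species order
SPECIES = [
    "O",      # free operator
    "RO",     # repressor-operator complex
    "IRO",    # singly induced complex
    "I2RO",   # doubly induced complex
    "R2",     # free repressor dimer
    "IR2",    # singly induced free dimer
    "I2R2",   # doubly induced free dimer
    "mY",     # lacY mRNA
    "Y",      # LacY protein
    "I",      # intracellular inducer
    "I_ext",  # extracellular inducer
    "YI",     # LacY-inducer transport complex
]

OPERATOR_STATES = ("O", "RO", "IRO", "I2RO")


@dataclass
class Reaction:
    """One elementary mass-action reaction.

    ``rate`` is the stored rate constant; for second-order reactions it is a
    molar constant (M^-1 s^-1) and the stochastic propensity constant is
    ``rate / (N_A * V)``.
    """

    name: str
    reactants: dict
    products: dict
    rate: float
    order: int  # 0, 1 or 2 (mass action)

    def propensity_constant(self, volume: float) -> float:
        if self.order == 2:
            return self.rate / (AVOGADRO * volume)
        return self.rate


@dataclass
class ReactionNetwork:
    """Species, reactions and clamping rules, ready for the SSA engine."""

    species: list
    reactions: list
    clamped: set
    volume: float
    variant: str
    inducer_kind: str
    compartments: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def reaction_index(self, name: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.name == name:
                return i
        raise KeyError(name)

    def to_arrays(self):
        """Stoichiometry and propensity arrays for the compiled SSA kernel.

        Returns (reactant_stoich, net_stoich, rate_constants, clamped_mask),
        with rate constants already converted to per-event propensity form.
        """
        ns, nr = self.n_species, self.n_reactions
        react = np.zeros((nr, ns), dtype=np.int64)
        net = np.zeros((nr, ns), dtype=np.int64)
        rates = np.zeros(nr)
        for i, rxn in enumerate(self.reactions):
            for sp, nu in rxn.reactants.items():
                react[i, self.species_index(sp)] = nu
                net[i, self.species_index(sp)] -= nu
            for sp, nu in rxn.products.items():
                net[i, self.species_index(sp)] += nu
            rates[i] = rxn.propensity_constant(self.volume)
        clamp = np.array([s in self.clamped for s in self.species])
        # a clamped species never changes count
        net[:, clamp] = 0
        return react, net, rates, clamp

    def initial_state(self, inducer_conc: float = 0.0,
                      protein: int = 0, mrna: int = 0) -> np.ndarray:
        """Default initial counts: free operator, all repressors free.

        ``inducer_conc`` (M) sets the clamped inducer pool — intracellular
        for NPF, extracellular for PFB.
        """
        counts = np.zeros(self.n_species, dtype=np.int64)
        counts[self.species_index("O")] = 1
        counts[self.species_index("R2")] = self._r_tot
        counts[self.species_index("mY")] = mrna
        counts[self.species_index("Y")] = protein
        n_inducer = int(round(inducer_conc * AVOGADRO * self.volume))
        target = "I" if self.variant == "NPF" else "I_ext"
        counts[self.species_index(target)] = n_inducer
        return counts

    _r_tot: int = 10


def build_lac_network(variant: str, inducer_kind: str,
                      rates: LacRates | None = None) -> ReactionNetwork:
    """Assemble the lac circuit reaction network for one model variant.

    Raises :class:`ConfigurationError` for unknown variant or inducer kind.
    """
    if variant not in ("NPF", "PFB"):
        raise ConfigurationError(f"unknown variant {variant!r}")
    if inducer_kind not in ("TMG", "IPTG"):
        raise ConfigurationError(f"unknown inducer kind {inducer_kind!r}")
    if rates is None:
        rates = LacRates.defaults(inducer_kind)
    rates.validate()

    rx: list[Reaction] = []

    def r(name, reactants, products, rate, order):
        rx.append(Reaction(name, reactants, products, rate, order))

    # operator binding / unbinding (Eqs of the repression subsystem)
    r("bind_R2", {"O": 1, "R2": 1}, {"RO": 1}, rates.k_rb, 2)
    r("bind_IR2", {"O": 1, "IR2": 1}, {"IRO": 1}, rates.k_irb, 2)
    r("bind_I2R2", {"O": 1, "I2R2": 1}, {"I2RO": 1}, rates.k_i2rb, 2)
    r("release_RO", {"RO": 1}, {"O": 1, "R2": 1}, rates.k_ro_off, 1)
    r("release_IRO", {"IRO": 1}, {"O": 1, "IR2": 1}, rates.k_iro_off, 1)
    r("release_I2RO", {"I2RO": 1}, {"O": 1, "I2R2": 1}, rates.k_i2ro_off, 1)

    # expression
    r("transcription", {"O": 1}, {"O": 1, "mY": 1}, rates.k_ts, 1)
    r("translation", {"mY": 1}, {"mY": 1, "Y": 1}, rates.k_tl, 1)
    r("mrna_degradation", {"mY": 1}, {}, rates.k_mdeg, 1)
    r("protein_dilution", {"Y": 1}, {}, rates.k_pdeg, 1)

    # inducer <-> free repressor (two independent sites)
    r("ind_on_free_1", {"I": 1, "R2": 1}, {"IR2": 1}, rates.inducer_on_free_1, 2)
    r("ind_off_free_1", {"IR2": 1}, {"I": 1, "R2": 1}, rates.inducer_off_free_1, 1)
    r("ind_on_free_2", {"I": 1, "IR2": 1}, {"I2R2": 1}, rates.inducer_on_free_2, 2)
    r("ind_off_free_2", {"I2R2": 1}, {"I": 1, "IR2": 1}, rates.inducer_off_free_2, 1)

    # inducer <-> repressor-operator complex (knock-off pathway)
    r("ind_on_cplx_1", {"I": 1, "RO": 1}, {"IRO": 1}, rates.inducer_on_cplx_1, 2)
    r("ind_off_cplx_1", {"IRO": 1}, {"I": 1, "RO": 1}, rates.inducer_off_cplx_1, 1)
    r("ind_on_cplx_2", {"I": 1, "IRO": 1}, {"I2RO": 1}, rates.inducer_on_cplx_2, 2)
    r("ind_off_cplx_2", {"I2RO": 1}, {"I": 1, "IRO": 1}, rates.inducer_off_cplx_2, 1)

    clamped = set()
    if variant == "PFB":
        # passive membrane diffusion
        r("diffusion_in", {"I_ext": 1}, {"I": 1}, rates.k_diff_in, 1)
        r("diffusion_out", {"I": 1}, {"I_ext": 1}, rates.k_diff_out, 1)
        # LacY transport, expanded Michaelis-Menten
        r("transport_bind", {"Y": 1, "I_ext": 1}, {"YI": 1}, rates.k_y_on, 2)
        r("transport_unbind", {"YI": 1}, {"Y": 1, "I_ext": 1}, rates.k_y_off, 1)
        r("transport_cat", {"YI": 1}, {"Y": 1, "I": 1}, rates.k_cat, 1)
        clamped.add("I_ext")
    else:
        clamped.add("I")

    compartments = {s: "intracellular" for s in SPECIES}
    compartments["I_ext"] = "extracellular"

    net = ReactionNetwork(
        species=list(SPECIES), reactions=rx, clamped=clamped,
        volume=rates.V, variant=variant, inducer_kind=inducer_kind,
        compartments=compartments,
    )
    net._r_tot = rates.R_tot
    return net
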