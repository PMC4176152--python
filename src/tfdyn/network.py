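"""Reaction network for the hormone-inducible LexA-ER-AD circuit.

The model tracks a chimeric transcription factor (bacterial LexA DNA-binding
domain, human estrogen-receptor hormone-binding domain, and one of four
activation domains), its hormone input (beta-estradiol), a cytoplasmic
inhibitory protein that retains the hormone-free factor, RNA polymerase II
(which both transcribes and, as a limiting resource, couples the circuit to
growth), the synthetic target promoter with 1-8 lexA operator boxes, and the
yellow/red fluorescent reporters.  The network is a fixed set of 29 species
and 57 elementary reactions; mass-action kinetics apply everywhere except the
activated-recruitment, translation and red-reporter-synthesis steps, which
carry dedicated rate laws evaluated by :mod:`tfdyn.dynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "VARIANTS",
    "MOIETIES",
    "COMPARTMENTS",
    "Species",
    "Reaction",
    "ReactionNetwork",
    "build_canonical_network",
    "stoichiometric_matrix",
    "conserved_totals",
    "write_reactions",
    "read_reactions",
    "ConfigurationError",
    "StructuralError",
]

VARIANTS = ("B42", "B112", "Gal4AD", "VP16")

MOIETIES = frozenset(
    {
        "TF",
        "hormone",
        "inhibitor",
        "Pol",
        "gene_TF",
        "gene_I",
        "gene_Pol",
        "gene_rep",
        "operator",
        "mRNA",
        "reporter",
        "red",
    }
)

COMPARTMENTS = ("medium", "cytoplasm", "nucleus")

RATE_LAWS = ("mass_action", "recruitment", "translation", "red_synthesis")


class ConfigurationError(ValueError):
    """Invalid user-facing configuration (variant, box count, ...)."""


class StructuralError(RuntimeError):
    """The assembled network violates a structural invariant."""


@dataclass(frozen=True)
class Species:
    """One chemical species (state variable) of the model.

    ``moieties`` counts the conserved building blocks the species contains;
    ``diluted`` species are subject to growth dilution at the instantaneous
    specific growth rate; ``clamped`` species have their time derivative
    forced to zero (used for the extracellular hormone, which is dosed in
    excess in an effectively infinite medium volume).
    """

    id: str
    compartment: str
    moieties: Dict[str, int] = field(default_factory=dict)
    diluted: bool = True
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ConfigurationError(f"unknown compartment {self.compartment!r}")
        unknown = set(self.moieties) - MOIETIES
        if unknown:
            raise ConfigurationError(f"unknown moieties {sorted(unknown)}")
        if self.clamped and self.diluted:
            raise ConfigurationError(f"clamped species {self.id} cannot be diluted")
        genic = {"gene_TF", "gene_I", "gene_Pol", "gene_rep", "operator"}
        if self.diluted and genic & set(self.moieties):
            raise ConfigurationError(
                f"gene/operator species {self.id} must not be diluted"
            )


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: educts -> products at ``rate_constant_id``.

    ``rate_law`` is ``mass_action`` for ordinary elementary steps;
    ``recruitment`` marks the activated polymerase-recruitment step at the
    target promoter, ``translation`` the growth-scaled translation steps and
    ``red_synthesis`` the growth-coupled constitutive red-reporter source.
    """

    educts: Dict[str, int]
    products: Dict[str, int]
    rate_constant_id: str
    rate_law: str = "mass_action"

    def __post_init__(self) -> None:
        if self.rate_law not in RATE_LAWS:
            raise ConfigurationError(f"unknown rate law {self.rate_law!r}")
        for side in (self.educts, self.products):
            for sid, mol in side.items():
                if not (isinstance(mol, int) and mol > 0):
                    raise ConfigurationError(
                        f"molecularity of {sid} must be a positive integer"
                    )
        if self.rate_law == "mass_action" and sum(self.educts.values()) > 2:
            raise ConfigurationError(
                "mass-action educt molecularity exceeds 2 "
                f"(reaction {self.rate_constant_id})"
            )


@dataclass
class ReactionNetwork:
    species: List[Species]
    reactions: List[Reaction]
    n_boxes: int
    variant: str

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("species ids must be unique")
        self._index = {sid: i for i, sid in enumerate(ids)}
        for r in self.reactions:
            for sid in list(r.educts) + list(r.products):
                if sid not in self._index:
                    raise ConfigurationError(f"reaction references unknown species {sid}")

    @property
    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    def index(self, species_id: str) -> int:
        return self._index[species_id]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def moiety_weights(self, moiety: str) -> np.ndarray:
        """Per-species copy number of ``moiety`` (integer weight vector)."""
        return np.array([s.moieties.get(moiety, 0) for s in self.species], dtype=float)


# ---------------------------------------------------------------------------
# canonical network assembly
# ---------------------------------------------------------------------------

def _canonical_species() -> List[Species]:
    S = Species
    return [
        S("H_ext", "medium", {"hormone": 1}, diluted=False, clamped=True),
        S("H_cyt", "cytoplasm", {"hormone": 1}, diluted=False),
        S("H_nuc", "nucleus", {"hormone": 1}, diluted=False),
        S("TF_cyt", "cytoplasm", {"TF": 1}),
        S("TFH_cyt", "cytoplasm", {"TF": 1, "hormone": 1}),
        S("I_cyt", "cytoplasm", {"inhibitor": 1}),
        S("TFI_cyt", "cytoplasm", {"TF": 1, "inhibitor": 1}),
        S("Pol_cyt", "cytoplasm", {"Pol": 1}),
        S("TF_nuc", "nucleus", {"TF": 1}),
        S("TFH_nuc", "nucleus", {"TF": 1, "hormone": 1}),
        S("Pol_nuc", "nucleus", {"Pol": 1}),
        S("TFHPol_nuc", "nucleus", {"TF": 1, "hormone": 1, "Pol": 1}),
        S("G_TF", "nucleus", {"gene_TF": 1}, diluted=False),
        S("G_TF_Pol", "nucleus", {"gene_TF": 1, "Pol": 1}, diluted=False),
        S("G_I", "nucleus", {"gene_I": 1}, diluted=False),
        S("G_I_Pol", "nucleus", {"gene_I": 1, "Pol": 1}, diluted=False),
        S("G_Pol", "nucleus", {"gene_Pol": 1}, diluted=False),
        S("G_Pol_Pol", "nucleus", {"gene_Pol": 1, "Pol": 1}, diluted=False),
        S("O_free", "nucleus", {"operator": 1}, diluted=False),
        S("O_TF", "nucleus", {"operator": 1, "TF": 1, "hormone": 1}, diluted=False),
        S("G_rep", "nucleus", {"gene_rep": 1}, diluted=False),
        S("G_rep_Pol", "nucleus", {"gene_rep": 1, "Pol": 1}, diluted=False),
        S("mRNA_TF", "cytoplasm", {"mRNA": 1}),
        S("mRNA_I", "cytoplasm", {"mRNA": 1}),
        S("mRNA_Pol", "cytoplasm", {"mRNA": 1}),
        S("mRNA_rep", "cytoplasm", {"mRNA": 1}),
        S("Rep_imm", "cytoplasm", {"reporter": 1}),
        S("Rep_mat", "cytoplasm", {"reporter": 1}),
        S("Red_mat", "cytoplasm", {"red": 1}),
    ]


def _canonical_reactions(variant: str) -> List[Reaction]:
    R = Reaction
    kd_ad = f"kd_ad_{variant.lower()}"
    rxns: List[Reaction] = [
        # hormone exchange with the (clamped, infinite) medium and the nucleus
        R({"H_ext": 1}, {"H_ext": 1, "H_cyt": 1}, "k_h_in"),
        R({"H_cyt": 1}, {}, "k_h_out"),
        R({"H_cyt": 1}, {"H_nuc": 1}, "k_h_nc"),
        R({"H_nuc": 1}, {"H_cyt": 1}, "k_h_cn"),
        # cytoplasmic retention of the hormone-free factor by the inhibitor
        R({"TF_cyt": 1, "I_cyt": 1}, {"TFI_cyt": 1}, "k_ti_on"),
        R({"TFI_cyt": 1}, {"TF_cyt": 1, "I_cyt": 1}, "k_ti_off"),
        # hormone binding in both compartments
        R({"TF_cyt": 1, "H_cyt": 1}, {"TFH_cyt": 1}, "k_th_on"),
        R({"TFH_cyt": 1}, {"TF_cyt": 1, "H_cyt": 1}, "k_th_off"),
        R({"TF_nuc": 1, "H_nuc": 1}, {"TFH_nuc": 1}, "k_th_on_n"),
        R({"TFH_nuc": 1}, {"TF_nuc": 1, "H_nuc": 1}, "k_th_off_n"),
        # nucleocytoplasmic transport
        R({"TFH_cyt": 1}, {"TFH_nuc": 1}, "k_tfh_in"),
        R({"TFH_nuc": 1}, {"TFH_cyt": 1}, "k_tfh_out"),
        R({"TF_nuc": 1}, {"TF_cyt": 1}, "k_tf_out"),
        R({"TF_cyt": 1}, {"TF_nuc": 1}, "k_tf_in"),
        R({"Pol_cyt": 1}, {"Pol_nuc": 1}, "k_pol_in"),
        # squelching: the activation domain sequesters free polymerase;
        # the dissociation rate is k_sq_on * Kd(AD), i.e. the variant's
        # AD-polymerase affinity sets the equilibrium
        R({"TFH_nuc": 1, "Pol_nuc": 1}, {"TFHPol_nuc": 1}, "k_sq_on"),
        R({"TFHPol_nuc": 1}, {"TFH_nuc": 1, "Pol_nuc": 1}, kd_ad),
    ]
    # constitutive genes (TF, inhibitor, polymerase); polymerase expression is
    # autocatalytic because its own transcription requires free Pol_nuc
    for x in ("TF", "I", "Pol"):
        g, gp, m = f"G_{x}", f"G_{x}_Pol", f"mRNA_{x}"
        lx = x.lower()
        rxns += [
            R({g: 1, "Pol_nuc": 1}, {gp: 1}, f"k_gb_{lx}"),
            R({gp: 1}, {g: 1, "Pol_nuc": 1}, f"k_gu_{lx}"),
            R({gp: 1}, {g: 1, "Pol_nuc": 1, m: 1}, f"k_tx_{lx}"),
        ]
    rxns += [
        # operator binding by the activated (hormone-bound, nuclear) factor
        R({"TFH_nuc": 1, "O_free": 1}, {"O_TF": 1}, "k_op_on"),
        R({"O_TF": 1}, {"TFH_nuc": 1, "O_free": 1}, "k_op_off"),
        # activated recruitment at the target promoter (steric rate law);
        # references the variant's AD-polymerase affinity
        R({"G_rep": 1, "Pol_nuc": 1}, {"G_rep_Pol": 1}, kd_ad, rate_law="recruitment"),
        # basal, activator-independent recruitment
        R({"G_rep": 1, "Pol_nuc": 1}, {"G_rep_Pol": 1}, "k_basal"),
        # target transcription releases the polymerase
        R({"G_rep_Pol": 1}, {"G_rep": 1, "Pol_nuc": 1, "mRNA_rep": 1}, "k_tx_rep"),
        # growth-scaled translation
        R({"mRNA_TF": 1}, {"mRNA_TF": 1, "TF_cyt": 1}, "k_tl_tf", rate_law="translation"),
        R({"mRNA_I": 1}, {"mRNA_I": 1, "I_cyt": 1}, "k_tl_i", rate_law="translation"),
        R({"mRNA_Pol": 1}, {"mRNA_Pol": 1, "Pol_cyt": 1}, "k_tl_pol", rate_law="translation"),
        R({"mRNA_rep": 1}, {"mRNA_rep": 1, "Rep_imm": 1}, "k_tl_rep", rate_law="translation"),
        # reporter maturation and the growth-coupled constitutive red reporter
        R({"Rep_imm": 1}, {"Rep_mat": 1}, "k_mat"),
        R({}, {"Red_mat": 1}, "k_red", rate_law="red_synthesis"),
        # mRNA turnover
        R({"mRNA_TF": 1}, {}, "k_deg_mtf"),
        R({"mRNA_I": 1}, {}, "k_deg_mi"),
        R({"mRNA_Pol": 1}, {}, "k_deg_mpol"),
        R({"mRNA_rep": 1}, {}, "k_deg_mrep"),
        # protein turnover (one constant per moiety class); turnover of the
        # operator- and promoter-bound complexes destroys the protein cargo
        # and regenerates the free DNA element
        R({"TF_cyt": 1}, {}, "k_deg_tf"),
        R({"TF_nuc": 1}, {}, "k_deg_tf"),
        R({"TFH_cyt": 1}, {}, "k_deg_tf"),
        R({"TFH_nuc": 1}, {}, "k_deg_tf"),
        R({"TFI_cyt": 1}, {}, "k_deg_tf"),
        R({"I_cyt": 1}, {}, "k_deg_i"),
        R({"Pol_cyt": 1}, {}, "k_deg_pol"),
        R({"Pol_nuc": 1}, {}, "k_deg_pol"),
        # the squelching complex is co-degraded at the unstable activator's
        # rate, draining captured polymerase (the toxicity-generating sink)
        R({"TFHPol_nuc": 1}, {}, "k_deg_tf"),
        R({"O_TF": 1}, {"O_free": 1}, "k_deg_tf"),
        R({"G_rep_Pol": 1}, {"G_rep": 1}, "k_deg_pol"),
        R({"Rep_imm": 1}, {}, "k_deg_rep"),
        R({"Rep_mat": 1}, {}, "k_deg_rep"),
        R({"Red_mat": 1}, {}, "k_deg_red"),
    ]
    return rxns


def build_canonical_network(variant: str, n_boxes: int) -> ReactionNetwork:
    """Assemble the fixed 29-species network for one construct.

    ``variant`` selects which AD-polymerase affinity parameter the squelching
    and activated-recruitment reactions reference; ``n_boxes`` (1-8) sets the
    total operator concentration and the exponent in the steric recruitment
    factor.  The species and reaction lists are identical for all variants.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; expected one of {VARIANTS}"
        )
    if not (isinstance(n_boxes, (int, np.integer)) and 1 <= n_boxes <= 8):
        raise ConfigurationError(f"n_boxes must be an integer in 1..8, got {n_boxes!r}")
    net = ReactionNetwork(
        species=_canonical_species(),
        reactions=_canonical_reactions(variant),
        n_boxes=int(n_boxes),
        variant=variant,
    )
    if net.n_species != 29:
        raise StructuralError(f"canonical network has {net.n_species} species, not 29")
    return net


def stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Integer stoichiometric matrix N (species x reactions).

    Entry (i, j) is the net molecularity change of species i in reaction j.
    Rows of clamped species are returned as-is; the dynamics module zeroes
    their derivatives.
    """
    N = np.zeros((net.n_species, net.n_reactions), dtype=np.int64)
    for j, r in enumerate(net.reactions):
        for sid, mol in r.educts.items():
            N[net.index(sid), j] -= mol
        for sid, mol in r.products.items():
            N[net.index(sid), j] += mol
    return N


_CONSERVED_MOIETIES = ("gene_TF", "gene_I", "gene_Pol", "gene_rep", "operator")


def conserved_totals(
    net: ReactionNetwork, initial_state: np.ndarray | None = None
) -> List[Tuple[str, np.ndarray, float]]:
    """Weight vectors w with w @ N == 0 for the gene and operator moieties.

    Returns ``(moiety, weights, total)`` triples; ``total`` is w . c0 when an
    initial state is given, else NaN.  Raises :class:`StructuralError` if any
    of the five DNA-element moieties is not conserved, which would indicate a
    defect in the reaction table.
    """
    N = stoichiometric_matrix(net)
    out = []
    for moiety in _CONSERVED_MOIETIES:
        w = net.moiety_weights(moiety)
        residual = w @ N
        if np.any(residual != 0):
            bad = [net.reactions[j].rate_constant_id for j in np.nonzero(residual)[0]]
            raise StructuralError(f"moiety {moiety} not conserved in reactions {bad}")
        total = float(w @ initial_state) if initial_state is not None else float("nan")
        out.append((moiety, w, total))
    return out


# ---------------------------------------------------------------------------
# serialization: one reaction per row, tab-separated
# ---------------------------------------------------------------------------

def _side_to_str(side: Dict[str, int]) -> str:
    if not side:
        return "-"
    return " + ".join(
        (f"{mol} {sid}" if mol != 1 else sid) for sid, mol in sorted(side.items())
    )


def _side_from_str(text: str) -> Dict[str, int]:
    text = text.strip()
    if text == "-" or not text:
        return {}
    side: Dict[str, int] = {}
    for term in text.split("+"):
        parts = term.split()
        if len(parts) == 1:
            sid, mol = parts[0], 1
        elif len(parts) == 2:
            sid, mol = parts[1], int(parts[0])
        else:
            raise ValueError(f"malformed reaction side term {term!r}")
        side[sid] = side.get(sid, 0) + mol
    return side


def write_reactions(net: ReactionNetwork, path) -> None:
    """Write the reaction table as delimited text (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# variant={net.variant}\tn_boxes={net.n_boxes}\n")
        fh.write("educts\tproducts\trate_constant_id\trate_law\n")
        for r in net.reactions:
            fh.write(
                f"{_side_to_str(r.educts)}\t{_side_to_str(r.products)}"
                f"\t{r.rate_constant_id}\t{r.rate_law}\n"
            )


def read_reactions(path) -> ReactionNetwork:
    """Read a reaction table written by :func:`write_reactions`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing metadata line")
        meta = dict(item.split("=") for item in header[1:].split())
        cols = fh.readline().strip().split("\t")
        if cols != ["educts", "products", "rate_constant_id", "rate_law"]:
            raise ValueError(f"unexpected column header {cols}")
        reactions = []
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 fields, got {len(fields)}")
            reactions.append(
                Reaction(
                    educts=_side_from_str(fields[0]),
                    products=_side_from_str(fields[1]),
                    rate_constant_id=fields[2],
                    rate_law=fields[3],
                )
            )
    return ReactionNetwork(
        species=_canonical_species(),
        reactions=reactions,
        n_boxes=int(meta["n_boxes"]),
        variant=meta["variant"],
    )
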