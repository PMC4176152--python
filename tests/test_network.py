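import numpy as np
import pytest

import tfdyn as td
from tfdyn.network import (
    ConfigurationError,
    Reaction,
    Species,
    StructuralError,
    VARIANTS,
    build_canonical_network,
    conserved_totals,
    read_reactions,
    stoichiometric_matrix,
    write_reactions,
)


@pytest.mark.parametrize("variant", VARIANTS)
@pytest.mark.parametrize("n_boxes", [1, 4, 8])
def test_canonical_network_has_29_states(variant, n_boxes):
    net = build_canonical_network(variant, n_boxes)
    assert net.n_species == 29
    assert stoichiometric_matrix(net).shape == (29, net.n_reactions)


def test_variants_are_structurally_isomorphic():
    """Changing the activation domain changes a parameter id, not structure."""
    a = build_canonical_network("B42", 4)
    b = build_canonical_network("VP16", 4)
    assert a.species == b.species
    assert len(a.reactions) == len(b.reactions)
    diffs = [
        (ra.rate_constant_id, rb.rate_constant_id)
        for ra, rb in zip(a.reactions, b.reactions)
        if ra != rb
    ]
    assert diffs and all(
        {ka, kb} == {"kd_ad_b42", "kd_ad_vp16"} for ka, kb in diffs
    )
    for ra, rb in zip(a.reactions, b.reactions):
        assert ra.educts == rb.educts and ra.products == rb.products


def test_stoichiometric_matrix_columns():
    net = build_canonical_network("B42", 4)
    N = stoichiometric_matrix(net)
    # bimolecular association: A + B -> C gives (-1, -1, +1)
    j = next(
        i for i, r in enumerate(net.reactions)
        if r.educts == {"TFH_nuc": 1, "O_free": 1} and r.products == {"O_TF": 1}
    )
    assert N[net.index("TFH_nuc"), j] == -1
    assert N[net.index("O_free"), j] == -1
    assert N[net.index("O_TF"), j] == 1
    # transcription releases gene and polymerase and makes one transcript
    j = next(
        i for i, r in enumerate(net.reactions)
        if r.educts == {"G_rep_Pol": 1} and "mRNA_rep" in r.products
    )
    col = N[:, j]
    assert col[net.index("G_rep_Pol")] == -1
    for sid in ("G_rep", "Pol_nuc", "mRNA_rep"):
        assert col[net.index(sid)] == 1
    assert np.abs(col).sum() == 4


def test_conserved_moieties_in_left_null_space(net_b42_4):
    N = stoichiometric_matrix(net_b42_4)
    totals = conserved_totals(net_b42_4)
    assert {m for m, _, _ in totals} >= {
        "gene_TF", "gene_I", "gene_Pol", "gene_rep", "operator"
    }
    for _, w, _ in totals:
        assert np.all(w @ N == 0)


@pytest.mark.parametrize("n_boxes", [1, 3, 8])
def test_operator_total_scales_with_box_count(n_boxes, params):
    net = build_canonical_network("B42", n_boxes)
    c0 = td.pre_equilibrate(td.Condition("B42", n_boxes, "SDC", 0.0), params)
    totals = dict(
        (m, t) for m, _, t in conserved_totals(net, c0)
    )
    gene_rep = totals["gene_rep"]
    assert totals["operator"] == pytest.approx(n_boxes * gene_rep, rel=1e-9)


def test_mass_action_educts_at_most_bimolecular(net_b42_4):
    for r in net_b42_4.reactions:
        if r.rate_law == "mass_action":
            assert sum(r.educts.values()) <= 2


@pytest.mark.parametrize(
    "variant,n_boxes",
    [("B99", 4), ("B42", 0), ("B42", 9), ("vp16", 4)],
)
def test_invalid_configuration_rejected(variant, n_boxes):
    with pytest.raises(ConfigurationError):
        build_canonical_network(variant, n_boxes)


def test_species_invariants():
    with pytest.raises(ConfigurationError):
        Species("X", "nucleus", {"gene_rep": 1}, diluted=True)
    with pytest.raises(ConfigurationError):
        Species("X", "medium", {"hormone": 1}, diluted=True, clamped=True)
    with pytest.raises(ConfigurationError):
        Reaction({"A": 1, "B": 2}, {"C": 1}, "k")  # trimolecular mass action


def test_reaction_table_round_trip(tmp_path, net_b42_4):
    path = tmp_path / "reactions.tsv"
    write_reactions(net_b42_4, path)
    back = read_reactions(path)
    assert back.variant == net_b42_4.variant
    assert back.n_boxes == net_b42_4.n_boxes
    assert back.reactions == net_b42_4.reactions
    assert back.species == net_b42_4.species


def test_broken_reconstruction_detected():
    net = build_canonical_network("B42", 4)
    # a reaction that destroys an operator box breaks moiety conservation
    net.reactions.append(Reaction({"O_free": 1}, {}, "k_bogus"))
    with pytest.raises(StructuralError):
        conserved_totals(net)


def test_default_parameters_cover_all_rate_constants(params):
    net = build_canonical_network("Gal4AD", 2)
    for r in net.reactions:
        assert r.rate_constant_id in params
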