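"""Scaffold chemistry: condensation, reductive loops, starters, emission."""

import pytest
from rdkit import Chem

from gnp._masses import H2O, monoisotopic_mass
from gnp.cluster_assembly import AssemblyModule
from gnp.scaffold_builder import (
    ChemistryError,
    Scaffold,
    attach_starter,
    build_scaffold,
    default_monomers,
    emit_structure,
    extend_ketide,
    extend_peptide,
)

N_METHYL = 14.01565
KR_DELTA = 2.01565


def has_substructure(smiles, smarts):
    return Chem.MolFromSmiles(smiles).HasSubstructMatch(Chem.MolFromSmarts(smarts))


class TestExtendPeptide:
    def test_diglycine_mass(self, monomers):
        chain = extend_peptide(extend_peptide(Scaffold(), monomers["gly"]), monomers["gly"])
        assert chain.monoisotopic_mass == pytest.approx(132.0535, abs=1e-4)
        assert chain.smiles == Chem.CanonSmiles("NCC(=O)NCC(O)=O")

    def test_n_methylation_adds_ch2(self, monomers):
        chain = extend_peptide(
            extend_peptide(Scaffold(), monomers["gly"]), monomers["gly"], n_methylated=True
        )
        assert chain.monoisotopic_mass == pytest.approx(146.0691, abs=1e-4)
        assert has_substructure(chain.smiles, "C(=O)N(C)C")

    def test_initialization_with_serine(self, monomers):
        chain = extend_peptide(Scaffold(), monomers["ser"])
        assert chain.monoisotopic_mass == pytest.approx(monomers["ser"].monoisotopic_mass, abs=1e-6)

    def test_ketide_unit_rejected(self, monomers):
        with pytest.raises(ChemistryError):
            extend_peptide(Scaffold(), monomers["mal"])


def acetyl_chain():
    """Two-carbon acyl start (acetate unit) for ketide extension tests."""
    return extend_ketide(Scaffold(), "mal")


class TestExtendKetide:
    def test_beta_keto(self):
        chain = extend_ketide(acetyl_chain(), "malonate", set())
        assert chain.smiles == Chem.CanonSmiles("CC(=O)CC(=O)O")  # acetoacetic acid

    def test_kr_gives_hydroxyl_with_alpha_methyl(self):
        chain = extend_ketide(acetyl_chain(), "methylmalonate", {"KR"})
        assert chain.smiles == Chem.CanonSmiles("CC(O)C(C)C(=O)O")
        assert has_substructure(chain.smiles, "[CH3][CH]([OX2H])")

    def test_kr_dh_gives_alkene(self):
        chain = extend_ketide(acetyl_chain(), "malonate", {"KR", "DH"})
        assert chain.smiles == Chem.CanonSmiles("CC=CC(=O)O")

    def test_full_reduction_gives_saturated(self):
        chain = extend_ketide(acetyl_chain(), "malonate", {"KR", "DH", "ER"})
        assert chain.smiles == Chem.CanonSmiles("CCCC(=O)O")

    def test_dh_without_kr_rejected(self):
        with pytest.raises(ChemistryError):
            extend_ketide(acetyl_chain(), "malonate", {"DH"})


class TestAttachStarter:
    def test_decanoyl_acylation(self, monomers):
        chain = extend_peptide(extend_peptide(Scaffold(), monomers["gly"]), monomers["gly"])
        acylated = attach_starter(chain, monomers["c10"])
        assert has_substructure(acylated.smiles, "CCCCCCCCCC(=O)NCC(=O)")
        expected = chain.monoisotopic_mass + monomers["c10"].monoisotopic_mass - H2O
        assert acylated.monoisotopic_mass == pytest.approx(expected, abs=1e-6)

    def test_unresolved_faal_gives_acyl_rsite(self, monomers):
        chain = extend_peptide(Scaffold(), monomers["ser"])
        acylated = attach_starter(chain, None)
        assert acylated.has_open_sites
        assert ("R_acyl", "unresolved fatty acyl starter") in acylated.site_labels

    def test_beta_hydroxy_myristoyl(self, monomers):
        chain = extend_peptide(Scaffold(), monomers["ser"])
        acylated = attach_starter(chain, monomers["c14-oh"])
        assert has_substructure(acylated.smiles, "CC(O)CC(=O)N")


def nrps(index, substrate, **kw):
    return AssemblyModule(index, "NRPS", [], substrate, **kw)


def pks(index, substrate, state=frozenset()):
    return AssemblyModule(index, "PKS", [], substrate, reductive_state=frozenset(state))


class TestBuildScaffold:
    def test_diglycine_from_modules(self, monomers):
        s = build_scaffold([nrps(1, "gly"), nrps(2, "gly")])
        assert s.smiles == Chem.CanonSmiles("NCC(=O)NCC(O)=O")

    def test_hybrid_nrps_pks(self, monomers):
        s = build_scaffold([nrps(1, "ser"), pks(2, "mmal", {"KR"}), nrps(3, "gly")])
        assert has_substructure(s.smiles, "NC(CO)C(O)C(C)C(=O)NCC(=O)O")

    def test_trans_modules_excluded_with_note(self, monomers):
        mods = [nrps(1, "gly"), AssemblyModule(2, "NRPS", [], "ser", trans_acting=True)]
        s = build_scaffold(mods)
        assert s.smiles == Chem.CanonSmiles("NCC(=O)O")
        assert any("trans-acting" in n for n in s.notes)

    def test_unknown_substrate_becomes_wildcard_site(self, monomers):
        s = build_scaffold([nrps(1, "gly"), nrps(2, "X")])
        assert s.has_open_sites
        with pytest.raises(ChemistryError):
            _ = s.monoisotopic_mass

    def test_determinism(self, monomers):
        mods = [nrps(1, "ser"), pks(2, "mal", {"KR", "DH"}), nrps(3, "val", n_methylated=True)]
        assert build_scaffold(mods).smiles == build_scaffold(mods).smiles


class TestMassAdditivity:
    @pytest.mark.parametrize(
        "codes,n_methyls",
        [(["gly", "ala", "ser"], 0), (["ser", "thr", "val", "phe"], 2), (["orn", "dab", "hse"], 1)],
    )
    def test_peptide_mass_bookkeeping(self, monomers, codes, n_methyls):
        chain = Scaffold()
        for i, c in enumerate(codes):
            chain = extend_peptide(chain, monomers[c], n_methylated=i < n_methyls)
        expected = (
            sum(monomers[c].monoisotopic_mass for c in codes)
            - (len(codes) - 1) * H2O
            + n_methyls * N_METHYL
        )
        assert chain.monoisotopic_mass == pytest.approx(expected, abs=1e-4)

    def test_reductive_deltas(self, monomers):
        base = extend_ketide(acetyl_chain(), "mal", set()).monoisotopic_mass
        kr = extend_ketide(acetyl_chain(), "mal", {"KR"}).monoisotopic_mass
        dh = extend_ketide(acetyl_chain(), "mal", {"KR", "DH"}).monoisotopic_mass
        er = extend_ketide(acetyl_chain(), "mal", {"KR", "DH", "ER"}).monoisotopic_mass
        assert kr - base == pytest.approx(KR_DELTA, abs=1e-4)
        assert dh - kr == pytest.approx(-H2O, abs=1e-4)
        assert er - dh == pytest.approx(KR_DELTA, abs=1e-4)


class TestEmit:
    def test_molfile_round_trip(self, monomers):
        s = build_scaffold([nrps(1, "ser"), nrps(2, "val")])
        smiles, molblock = emit_structure(s)
        back = Chem.MolToSmiles(Chem.MolFromMolBlock(molblock))
        assert back == smiles

    def test_rsite_preserved(self, monomers):
        s = build_scaffold([nrps(1, "gly"), nrps(2, "X")])
        smiles, molblock = emit_structure(s)
        assert "*" in smiles and ("R" in molblock or "*" in molblock)
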