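"""Synthetic cetacean worked example: tree, habitats and the ND2 site-297
states.

Everything here is a *synthetic stand-in* constructed from published,
well-established cetacean relationships and from the residue/codon states
reported for NADH dehydrogenase subunit 2 position 297 (Thr in 22 marine
taxa, Val in the two *Globicephala*, Ala in the five freshwater taxa plus
*Grampus griseus* and *Pseudorca crassidens*; ACC = Thr in *Sotalia
guianensis*, GCC = Ala in *S. fluviatilis*, GCT = Ala in *Inia
geoffrensis*).  The tree was not estimated from sequence data in this
package; branch lengths are plausible placeholders.  It exists so the
convergence machinery can be exercised on the canonical worked example
without downloading mitogenomes.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .alignments import CodonAlignment, HabitatAnnotation
from .codes import load_genetic_code

#: site-297 codon per taxon (codon -> residue via the mitochondrial code)
SITE297_CODONS: dict[str, str] = {
    # freshwater / riverine taxa — Ala
    "Inia_geoffrensis": "GCT",
    "Pontoporia_blainvillei": "GCC",
    "Lipotes_vexillifer": "GCC",
    "Sotalia_fluviatilis": "GCC",
    "Orcaella_brevirostris_Mekong": "GCC",
    # marine taxa carrying Ala
    "Grampus_griseus": "GCC",
    "Pseudorca_crassidens": "GCC",
    # marine taxa carrying Val
    "Globicephala_melas": "GTC",
    "Globicephala_macrorhynchus": "GTC",
    # marine taxa carrying Thr (22)
    "Sotalia_guianensis": "ACC",
    "Sousa_chinensis": "ACC",
    "Stenella_attenuata": "ACC",
    "Stenella_frontalis": "ACC",
    "Stenella_longirostris": "ACC",
    "Stenella_coeruleoalba": "ACC",
    "Delphinus_capensis": "ACC",
    "Tursiops_truncatus": "ACC",
    "Tursiops_aduncus": "ACC",
    "Lagenorhynchus_obliquidens": "ACC",
    "Lagenorhynchus_albirostris": "ACC",
    "Cephalorhynchus_heavisidii": "ACC",
    "Orcinus_orca": "ACC",
    "Orcaella_heinsohni": "ACC",
    "Feresa_attenuata": "ACC",
    "Peponocephala_electra": "ACC",
    "Phocoena_phocoena": "ACC",
    "Neophocaena_phocaenoides": "ACC",
    "Delphinapterus_leucas": "ACC",
    "Monodon_monoceros": "ACC",
    "Physeter_macrocephalus": "ACC",
    "Balaenoptera_physalus": "ACC",
}

RIVERINE = (
    "Inia_geoffrensis",
    "Pontoporia_blainvillei",
    "Lipotes_vexillifer",
    "Sotalia_fluviatilis",
    "Orcaella_brevirostris_Mekong",
)

# Odontocete backbone: sperm whale early-diverging; Lipotes before Inioidea
# (Inia + Pontoporia); Delphinoidea = Monodontidae + Phocoenidae +
# Delphinidae; Globicephalinae holds Grampus, Pseudorca, Feresa,
# Peponocephala and the two Globicephala.  Balaenoptera roots the tree.
# Branch lengths are placeholders (substitutions/site).
CETACEA_NEWICK = """(
 Balaenoptera_physalus:0.10,
 (
  Physeter_macrocephalus:0.09,
  (
   (Lipotes_vexillifer:0.07,
    (Inia_geoffrensis:0.05,Pontoporia_blainvillei:0.05):0.02):0.015,
   (
    (Delphinapterus_leucas:0.03,Monodon_monoceros:0.03):0.03,
    (Phocoena_phocoena:0.025,Neophocaena_phocaenoides:0.025):0.035,
    (
     (Orcinus_orca:0.035,
      (Orcaella_brevirostris_Mekong:0.015,Orcaella_heinsohni:0.015):0.02):0.008,
     (
      (Grampus_griseus:0.02,Pseudorca_crassidens:0.02):0.008,
      ((Feresa_attenuata:0.015,Peponocephala_electra:0.015):0.006,
       (Globicephala_melas:0.008,Globicephala_macrorhynchus:0.008):0.012):0.006
     ):0.01,
     (
      (Lagenorhynchus_obliquidens:0.02,Cephalorhynchus_heavisidii:0.02):0.008,
      Lagenorhynchus_albirostris:0.028,
      (
       (Sousa_chinensis:0.018,
        (Sotalia_fluviatilis:0.008,Sotalia_guianensis:0.008):0.01):0.005,
       (
        (Tursiops_truncatus:0.01,Tursiops_aduncus:0.01):0.006,
        (Stenella_attenuata:0.012,Stenella_frontalis:0.012):0.004,
        (Delphinus_capensis:0.014,
         (Stenella_longirostris:0.01,Stenella_coeruleoalba:0.01):0.004):0.002
       ):0.007
      ):0.006
     ):0.012
    ):0.02
   ):0.02
  ):0.02
 ):0.02
);"""


def cetacea_tree() -> dendropy.Tree:
    """The synthetic 31-tip cetacean topology."""
    return dendropy.Tree.get(data=CETACEA_NEWICK, schema="newick", preserve_underscores=True)


def cetacea_habitat() -> HabitatAnnotation:
    return HabitatAnnotation({t: ("riverine" if t in RIVERINE else "marine")
                              for t in SITE297_CODONS})


def site297_states() -> dict[str, str]:
    """Residue at site 297 per taxon (translated from the codon table)."""
    code = load_genetic_code("vertebrate_mitochondrial")
    return {t: code.codon_to_aa[c] for t, c in SITE297_CODONS.items()}


def site297_alignment() -> CodonAlignment:
    """A one-column codon alignment holding the site-297 codons."""
    code = load_genetic_code("vertebrate_mitochondrial")
    taxa = list(SITE297_CODONS)
    states = np.array([[code.index[SITE297_CODONS[t]]] for t in taxa],
                      dtype=np.int16)
    return CodonAlignment(taxa=taxa, codons=states, code=code, gene="ND2")
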