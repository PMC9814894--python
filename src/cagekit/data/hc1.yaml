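# HC1 building block: one quarter of the octa-anionic water-soluble
# hemicarcerand host, treated as a residue with head atom C1 and tail
# atom C20 (analogous to a truncated amino acid).
#
# The atom set, head/tail designation, cross-link atoms (C4, O5, O16a,
# C18a, C17a, C6b) and the 22 cavity-lining atom names are transcribed
# from the published residue definition.  The full intra-residue bond
# list is only drawn, not enumerated, in the source figure; connectivity
# below completes the drawn junctions chemically plausibly (main chain
# C1..C20, acetal-bridge side atoms, the di-anionic isophthalate linker
# ring with two carboxylates and two methyls).  Treat bonds not anchored
# by a printed junction as distilled-with-completion, not authoritative;
# no stereochemistry is implied.  Hydrogens are omitted (heavy-atom
# template); the cavity list is heavy-atom only.
name: HC1
head: C1
tail: C20
atoms:
  - {name: C1,   element: C, role: junction}
  - {name: C2,   element: C, role: main-chain}
  - {name: C3,   element: C, role: main-chain}
  - {name: C4,   element: C, role: main-chain}
  - {name: C5,   element: C, role: main-chain}
  - {name: C6,   element: C, role: main-chain}
  - {name: C7,   element: C, role: main-chain}
  - {name: C8,   element: C, role: main-chain}
  - {name: C9,   element: C, role: main-chain}
  - {name: C10,  element: C, role: main-chain}
  - {name: C11,  element: C, role: main-chain}
  - {name: C12,  element: C, role: main-chain}
  - {name: C13,  element: C, role: main-chain}
  - {name: C14,  element: C, role: main-chain}
  - {name: C15,  element: C, role: main-chain}
  - {name: C16,  element: C, role: main-chain}
  - {name: C17,  element: C, role: main-chain}
  - {name: C18,  element: C, role: main-chain}
  - {name: C19,  element: C, role: main-chain}
  - {name: C20,  element: C, role: junction}
  - {name: C6a,  element: C, role: side-chain}
  - {name: C6b,  element: C, role: side-chain}
  - {name: C16a, element: C, role: side-chain}
  - {name: C17a, element: C, role: side-chain}
  - {name: C18a, element: C, role: side-chain}
  - {name: O5,   element: O, role: side-chain}
  - {name: O6a,  element: O, role: side-chain}
  - {name: O7,   element: O, role: side-chain}
  - {name: O15,  element: O, role: side-chain}
  - {name: O16a, element: O, role: side-chain}
  - {name: O17,  element: O, role: side-chain}
  - {name: C9a,  element: C, role: side-chain}
  - {name: O9a,  element: O, role: side-chain}
  - {name: O9b,  element: O, role: side-chain}
  - {name: C11a, element: C, role: side-chain}
  - {name: O11a, element: O, role: side-chain}
  - {name: O11b, element: O, role: side-chain}
  - {name: C10a, element: C, role: side-chain}
  - {name: C12a, element: C, role: side-chain}
bonds:
  # main chain
  - [C1, C2]
  - [C2, C3]
  - [C3, C4]
  - [C4, C5]
  - [C5, C6]
  - [C6, C7]
  - [C7, C8]
  - [C8, C9]
  - [C9, C10]
  - [C10, C11]
  - [C11, C12]
  - [C12, C13]
  - [C13, C14]
  - [C14, C15]
  - [C15, C16]
  - [C16, C17]
  - [C17, C18]
  - [C18, C19]
  - [C19, C20]
  # linker aromatic ring closure
  - [C8, C13]
  # resorcinarene-side oxygens and acetal-bridge arms
  - [C5, O5]
  - [C6, C6a]
  - [C6a, O6a]
  - [C6a, C6b]
  - [C7, O7]
  - [C15, O15]
  - [C16, C16a]
  - [C16a, O16a]
  - [C17, O17]
  - [C17, C17a]
  - [C18, C18a]
  # isophthalate carboxylates (deprotonated; block net charge -2) and methyls
  - [C9, C9a]
  - [C9a, O9a]
  - [C9a, O9b]
  - [C11, C11a]
  - [C11a, O11a]
  - [C11a, O11b]
  - [C10, C10a]
  - [C12, C12a]
cavity_atoms:
  [C1, C2, C3, C4, C5, C6, C6a, O5, O6a, O7, C6b, C18a,
   C16, C17, C18, C19, C20, C16a, O15, O16a, O17, C17a]
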