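# Assembly spec for the four-fold symmetric octa-anionic host: four HC1
# building blocks joined tail-to-head, cyclized, plus three cross-link
# rules each applied at all four residue positions (12 cross-link bonds).
sequence: [HC1, HC1, HC1, HC1]
cyclic: true
cross_links:
  - {from_atom: C4,   to_atom: C18a, offset: 1}
  - {from_atom: O5,   to_atom: C17a, offset: 1}
  - {from_atom: O16a, to_atom: C6b,  offset: 1}
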