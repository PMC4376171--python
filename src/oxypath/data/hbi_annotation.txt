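# Default HbI (Scapharca inaequivalvis dimeric hemoglobin) annotation.
# Helix boundaries: globin fold of the 3SDH structure; residue numbering
# follows the deposited files (1-based, 146 residues per chain).
# These defaults are replaceable: pass your own annotation file to override.
helix A A 4 18
helix A B 21 36
helix A C 37 44
helix A D 45 51
helix A E 55 76
helix A F 84 98
helix A G 100 117
helix A H 121 145
helix B A 4 18
helix B B 21 36
helix B C 37 44
helix B D 45 51
helix B E 55 76
helix B F 84 98
helix B G 100 117
helix B H 121 145
corner A FG 97 100
corner B FG 97 100

# Xenon-cavity and distal-pocket linings (xenon-binding crystallography);
# marked replaceable -- membership cutoff 4.5 A to the per-frame centroid.
cavity B 4.5
  A 36
  A 37
  A 69
  A 97
end
cavity B 4.5
  B 36
  B 37
  B 69
  B 97
end
cavity Xe4 4.5
  A 25
  A 32
  A 35
  A 121
  A 124
end
cavity Xe4 4.5
  B 25
  B 32
  B 35
  B 121
  B 124
end
cavity Xe2 4.5
  A 7
  A 10
  A 90
  A 94
  A 114
end
cavity Xe2 4.5
  B 7
  B 10
  B 90
  B 94
  B 114
end
cavity Xe1 4.5
  A 89
  A 93
  A 104
  A 139
end
cavity Xe1 4.5
  B 89
  B 93
  B 104
  B 139
end
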