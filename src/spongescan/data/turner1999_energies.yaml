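# Nearest-neighbor free-energy parameters for intermolecular RNA duplexes
# at 37 C, kcal/mol.  Stacking free energies, loop initiation costs, the
# Ninio asymmetry rule, duplex initiation and the terminal A:U/G:U penalty
# are transcribed from the Turner/Mathews 1999 rule set as distributed in
# the ViennaRNA parameter file rna_turner1999.par (energies there are in
# dekacal/mol; divided by 100 here).
#
# stack[p1][p2]: p1 is the outer pair 5'X/3'Y on (strand1, strand2); p2 is
# the inner pair given 3'->5', i.e. the energy of the step
#   5'-A B-3'   (strand 1)
#   3'-U V-5'   (strand 2)
# is stack[t(A,U)][t(V,B)] with pair types ordered CG, GC, GU, UG, AU, UA.
pair_order: [CG, GC, GU, UG, AU, UA]
stack:
  - [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10]
  - [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40]
  - [-2.10, -2.50,  1.30, -0.50, -1.40, -1.30]
  - [-1.40, -1.50, -0.50,  0.30, -0.60, -1.00]
  - [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90]
  - [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30]
# bulge[n]: initiation cost of a bulge of n unpaired nucleotides (n = 1..15).
# A length-1 bulge additionally keeps the stacking term of its closing pairs.
bulge: [3.80, 2.80, 3.20, 3.60, 4.00, 4.40, 4.59, 4.70, 4.80, 4.90, 5.00, 5.10, 5.19, 5.27, 5.34]
# internal[n]: initiation cost of an internal loop with n unpaired
# nucleotides in total (n = 2..15).  Sizes 2-3 are the generic table values;
# the special 1x1/1x2 tabulations of the full rule set are not used here.
internal: [4.10, 5.10, 1.70, 1.80, 2.00, 2.20, 2.30, 2.40, 2.50, 2.60, 2.70, 2.78, 2.86, 2.94]
# asymmetric internal loops: + min(ninio_max, ninio_m * |n1 - n2|)
ninio_m: 0.50
ninio_max: 3.00
duplex_init: 4.10
terminal_au: 0.50
max_bulge: 15
max_internal: 15
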