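# Nearest-neighbor stacking free-energy increments at 37 C, kcal/mol.
# motif "XY/ZW": top strand 5'-XY-3', bottom strand aligned beneath it and
# written 3'-ZW-5', so X pairs Z and Y pairs W.  Only one member of each
# symmetry-equivalent motif pair is listed; the loader closes the table
# under the physical symmetry XY/ZW == WZ/YX.
# Watson-Crick/Watson-Crick values: Xia et al. 1998 duplex parameters.
# G.U wobble values: Turner-style estimates (same sign conventions); the
# table is a swappable asset and downstream statistics use relative
# energies only.
motif	dg37
AA/UU	-0.93
AU/UA	-1.10
UA/AU	-1.33
CU/GA	-2.08
CA/GU	-2.11
GU/CA	-2.24
GA/CU	-2.35
CG/GC	-2.36
GG/CC	-3.26
GC/CG	-3.42
AG/UU	-0.55
AU/UG	-1.36
UG/AU	-1.00
GA/UU	-1.27
CG/GU	-1.41
CU/GG	-2.11
GG/CU	-1.53
GU/CG	-2.51
GG/UU	-0.50
GU/UG	0.47
UG/GU	-0.57
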