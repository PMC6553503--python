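# Characterized-gene fixture (synthetic)

Versioned, synthetic stand-in data for the characterized transcription-factor
worked example: 92 records — 39 singleton-clade genes, 14 genes without
unique probes, 39 analyzable closest-paralog pairs — with one family tree per
record (family name stored as the newick root label).

Pair records carry a *target* correlation: the three named pairs use the
reference values −0.09, 0.24 and 0.92; all other pairs sit at the midpoint of
their histogram bin (−0.125, 0.125, 0.375, 0.625, 0.875), yielding bin counts
4/11/11/10/3 over the right-closed bins [−0.25,0], (0,0.25], (0.25,0.5],
(0.5,0.75], (0.75,1].  Expression vectors realizing these correlations are
not stored; `ricetf.synthetic.make_characterized_fixture` synthesizes them
deterministically at load time and measures the correlations from the
vectors.  All locus identifiers other than the printed reference loci are
synthetic placeholders.
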