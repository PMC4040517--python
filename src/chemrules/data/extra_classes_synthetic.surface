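# Synthetic, reconstructed class definitions (surface syntax).
#
# These stubs are reconstructed from ChEBI-style textual class descriptions;
# they are NOT part of the validated core registry and are not exercised by
# the default pipeline.  Load them with chemrules.classes.load_extra_classes().

halogenAtom SuperClassOf f OR cl OR br OR i

organicHalogenCompound SuperClassOf hasAtom SOME GraphNL ( Nodes ( 1 c , 2 halogenAtom ) Edges ( 1 2 bond ) )

exactlyOneAtom SuperClassOf molecule AND NOT polyatomicEntity

nitrogenEntity SuperClassOf hasAtom SOME n

ketone SuperClassOf molecule AND ( hasAtom SOME GraphNL ( Nodes ( 1 c , 2 o , 3 c , 4 c ) DisjointNodes ( 3 , 4 ) Edges ( 1 2 double , 1 3 single , 1 4 single ) ) )

amine SuperClassOf molecule AND ( hasAtom SOME GraphNL ( Nodes ( 1 n NOT positive , 2 c ) Edges ( 1 2 single ) ) )
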