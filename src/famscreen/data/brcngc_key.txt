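# Consensus motif key recognizing the BrCNGC family, spanning the PBC and
# hinge region of the cyclic-nucleotide-binding domain; derived from multiple
# sequence alignment of the family at >90% conservation.  Stored verbatim in
# the printed mixed dash/space style the parser is required to accept.
[[L] – X (2)—[G] –X (3)-[G] –X (1,2)-L -L -X -W –X (0,1,2)-[L] –X (7,14)-[P] –X (1,5)-S-X (10)-[E] -X -[F] -X –L]
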