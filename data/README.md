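# External data

`palaeognath_shl.nex` (not bundled): the published optimisation input for
the palaeognath syrinx/hyoid/larynx (SHL) character set — a PAUP-style
NEXUS file containing the character matrix (43 characters; the 43rd,
cranial character is excluded from optimisation), an ASSUMPTIONS block
marking the 18 ordered characters, and a TREES block with the
morphological, molecular and combined-data topologies.  It is distributed
with the original study's supplementary material and is subject to that
publication's terms, so it is not redistributed here.

Place the file at `data/palaeognath_shl.nex` to enable the reproduction
tests in `tests/test_acceptance.py` (`TestPublishedReproduction`); all
other tests are fully self-contained.
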