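# Rows of the packaged market table whose printed concordance label cannot
# be re-derived mechanically from the putative and final name text alone
# (genus-rank putatives labeled "Species confirmed", two-candidate final
# identifications, epithet changes absorbed as subspecies, or a printed
# label inconsistent with the final taxon). Tallies always use the printed
# label; the concordance classifier is cross-checked only on rows not
# listed here.
EM357
EM358
EM363
EM364
EM365
EM366
EM367
EM372
EM376
EM387
EM395
EM403
EM411
EM421
EM428
EM431
EM432
EM434
EM437
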