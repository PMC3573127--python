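# HVR-I haplogroup-diagnostic motif table.
#
# Each entry maps a haplogroup label to the set of HVR-I variants (rCRS
# position + derived base) that diagnose it.  Entries are ordered
# most-derived-first: assignment returns the first haplogroup whose full
# motif is contained in a haplotype's resolved variant set.  The table is an
# editable artifact: diagnostic motifs follow standard HVR-I usage and can be
# extended without touching code.  The final entry (H, empty motif) acts as
# the root/fallback class: an rCRS-identical HVR-I sequence is assigned H.
#
# coding_class gives the haplogroup-level outcome expected from the
# 22-SNP coding-region assay, used for HVR-I/coding consistency checks.
motifs:
  - label: Z1a
    variants: [16129A, 16185T, 16223T, 16224C, 16260T, 16298C]
  - label: C5
    variants: [16148T, 16223T, 16288C, 16298C, 16327T]
  - label: C1
    variants: [16189C, 16223T, 16298C, 16325C, 16327T]
  - label: U5a1
    variants: [16192T, 16256T, 16270T, 16399G]
  - label: U5b1b1a            # the 'Saami motif'
    variants: [16144C, 16189C, 16270T]
  - label: U2e
    variants: [16129C, 16189C, 16362C]
  - label: "C*"
    variants: [16223T, 16298C, 16327T]
  - label: U5a
    variants: [16192T, 16256T, 16270T]
  - label: I
    variants: [16129A, 16223T, 16391A]
  - label: X
    variants: [16189C, 16223T, 16278T]
  - label: A
    variants: [16223T, 16290T, 16319A]
  - label: U4a1
    variants: [16134T, 16356C]
  - label: "D*"
    variants: [16223T, 16362C]
  - label: "T*"
    variants: [16126C, 16294T]
  - label: J
    variants: [16069T, 16126C]
  - label: K
    variants: [16224C, 16311C]
  - label: W
    variants: [16223T, 16292T]
  - label: U5b
    variants: [16189C, 16270T]
  - label: U4
    variants: [16356C]
  - label: V
    variants: [16298C]
  - label: H
    variants: []
coding_class:
  U2e: U
  U4: U
  U4a1: U
  U5a: U
  U5a1: U
  U5b: U
  U5b1b1a: U
  C1: C
  "C*": C
  C5: C
  Z1a: M
  H: H
  "T*": T
  "D*": D
  V: V
  J: J
  K: U
  I: I
  X: X
  W: W
  A: A
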