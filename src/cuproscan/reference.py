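"""Reference segments of the R. capsulatus cutFOG system.

Published mutant constructs for this system delete two precisely defined
segments; their sequences are reproduced here so deletion lengths and
motif positions can be checked programmatically.

* ``CUTO_MRS``: the methionine-rich segment (MRS) between cupredoxin
  domains 1 and 2 of the multicopper oxidase CutO, removed in the
  delta-MRS variant.  The MRS carries auxiliary Cu-binding methionines.
* ``CUTF_CTERM_PP``: the proline-rich C-terminus of the Cu chaperone CutF
  (residues 109-118 of the 118-residue protein), removed in the
  C-terminal truncation variant.  It contains the conserved PP motif.
* ``CUTF_MOTIF``: the central cysteine motif of CutF (C69-X-X-H72-C73), a
  CXXXC-type motif with a histidine at the second X.
"""

CUTO_MRS = "MDHGAMDHSATPMQGMDGMADMMSLPGMAEMHAAMEGGLSM"

CUTF_CTERM_PP = "PEPEGPPPRL"

CUTF_MOTIF = "CXXHC"

CUTF_LENGTH_AA = 118  # full-length CutF precursor


def mrs_length() -> int:
    """Number of residues removed in the CutO delta-MRS construct."""
    return len(CUTO_MRS)


def cutf_cterm_deletion_length() -> int:
    """Number of residues removed in the CutF C-terminal truncation."""
    return len(CUTF_CTERM_PP)
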