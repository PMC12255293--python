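"""Bundled synthetic reference design used by examples, sweeps and reports.

The sequences are a synthetic stand-in modelled on the KRAS codon-12 context
(G12D-like c.35G>A substitution, probe matched to the mutant allele): a
realistic SNV neighbourhood for a discrimination probe, not a wet-lab
validated design.  The interrogated base sits at the last position of the
toehold; requesting a longer toehold extends the window further 5' of the
mutation so the junction placement is preserved.
"""

from __future__ import annotations

from .strand_model import MutationSpec, ProbeSystem, build_probe_system

# 11 nt immediately 5' of the interrogated base (supports toeholds up to 12 nt)
UPSTREAM = "TAGTTGGAGCT"
#: probe-matched (mutant) allele at the interrogated position
MATCHED_BASE = "A"
#: mismatched (wild-type) allele
MISMATCHED_BASE = "G"
# 20 nt branch-migration context 3' of the interrogated base
DOWNSTREAM = "TGGCGTAGGCAAGAGTGCCT"
# helper-anchor (association) context, 5'-proximal part used first
ASSOCIATION = "ACGATACAGCTAATTCAGAATCAT"

DEFAULT_TOEHOLD_LEN = 8
DEFAULT_BM_LEN = 20
DEFAULT_N_CLOSE = 1
DEFAULT_ASSOC_LEN = 16

#: standard assay concentrations: 250 nM target, probe and helper
DEFAULT_CONC = 250e-9
#: standard assay endpoint (1 h)
DEFAULT_T_END = 3600.0


def reference_system(
    toehold_len: int = DEFAULT_TOEHOLD_LEN,
    n_close: int = DEFAULT_N_CLOSE,
    bm_len: int = DEFAULT_BM_LEN,
    spacer_len: int = 2,
    spacer_pos: str = "bottom",
    rev_toehold_len: int = 0,
    assoc_len: int = DEFAULT_ASSOC_LEN,
) -> ProbeSystem:
    """Build the reference probe system for the requested design parameters."""
    if toehold_len < 1 or toehold_len > len(UPSTREAM) + 1:
        raise ValueError(f"toehold_len must be in [1, {len(UPSTREAM) + 1}]")
    if bm_len > len(DOWNSTREAM):
        raise ValueError(f"bm_len must be <= {len(DOWNSTREAM)}")
    if assoc_len > len(ASSOCIATION):
        raise ValueError(f"assoc_len must be <= {len(ASSOCIATION)}")
    target = (
        UPSTREAM[len(UPSTREAM) - (toehold_len - 1) :]
        + MATCHED_BASE
        + DOWNSTREAM[:bm_len]
        + ASSOCIATION[:assoc_len]
    )
    mut = MutationSpec(position=toehold_len - 1, ref_base=MATCHED_BASE, alt_base=MISMATCHED_BASE)
    return build_probe_system(
        target,
        mut,
        toehold_len=toehold_len,
        bm_len=bm_len,
        spacer_len=spacer_len,
        spacer_pos=spacer_pos,
        n_close=n_close,
        rev_toehold_len=rev_toehold_len,
    )


def association_series(lengths: tuple[int, ...] = (8, 10, 12, 14, 16, 18, 20, 22, 24)) -> dict[int, str]:
    """Association-domain length series (helper-anchor binding-affinity sweep)."""
    out = {}
    for n in lengths:
        if n > len(ASSOCIATION):
            raise ValueError(f"association context is only {len(ASSOCIATION)} nt")
        out[n] = ASSOCIATION[:n]
    return out
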