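"""Pipeline cut-offs shared by the copy-number and expression stages."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PipelineThresholds:
    """Cut-off values applied along the gene-selection funnel.

    All comparisons against these values are strict (``>``):

    ratio_cutoff
        A gene is classed as copy-number gained (CNG) when its
        gain/loss sample ratio exceeds this value, and copy-number lost
        (CNL) symmetrically.  Default 2, i.e. at least twice as many
        gained as lost samples.
    min_cng_samples
        A CNG gene is "frequent" only if more than this many samples
        carry a gain call.  Default 30.
    z_cutoff
        A sample is called over-expressed for a gene when its expression
        Z-score exceeds this value (under-expressed below the negated
        value).  Default 2 reference standard deviations.
    min_concordant_samples
        A frequent-CNG gene becomes a key gene when more than this many
        samples are simultaneously gained and over-expressed.
        Default 20.
    """

    ratio_cutoff: float = 2.0
    min_cng_samples: int = 30
    z_cutoff: float = 2.0
    min_concordant_samples: int = 20

    def __post_init__(self) -> None:
        for name in ("ratio_cutoff", "min_cng_samples", "z_cutoff",
                     "min_concordant_samples"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"threshold {name!r} must be > 0, got {value!r}")
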