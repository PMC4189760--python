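"""Small shared DNA helpers."""

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase IUPAC DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]
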