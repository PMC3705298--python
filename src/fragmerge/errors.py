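"""Exception hierarchy for fragment merging.

All user-facing failures raise a subclass of :class:`FragmergeError` so the
command-line layer can catch one type, report the offending fragment, and
exit non-zero.
"""


class FragmergeError(Exception):
    """Base class for all errors raised by this package."""


class AbifError(FragmergeError):
    """Malformed or unreadable ABIF (AB1) trace file."""


class FastaError(FragmergeError):
    """Malformed FASTA input."""


class TrimmedToZeroError(FragmergeError):
    """A chromatogram was trimmed to length zero; no merge is performed."""


class MergeError(FragmergeError):
    """Invalid input to a pairwise or chained merge."""


class SlideError(FragmergeError):
    """The slide motif was not found in the circular sequence."""


class SyntheticError(FragmergeError):
    """Infeasible synthetic-data request (motif placement, tiling)."""


class ConfigError(FragmergeError):
    """Invalid run configuration or undetectable input type."""
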