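"""Exception hierarchy.

All failures raised by this package derive from :class:`VcfMergeError` so
callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""


class VcfMergeError(Exception):
    """Base class for all errors raised by vcfmerge."""


class InputError(VcfMergeError):
    """A required input file is missing or unreadable."""


class FormatError(VcfMergeError):
    """An input file violates its format contract (columns, bounds, counts)."""


class SortOrderError(FormatError):
    """Variant positions decrease within one input file."""


class DuplicateVariantError(FormatError):
    """The same variant key occurs twice within a single batch."""


class DesyncError(VcfMergeError):
    """A variant announced by a batch's info table was not found in its VCF."""


class MergeError(VcfMergeError):
    """Inconsistency detected while splicing rows (e.g. FORMAT conflict)."""
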