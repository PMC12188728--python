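"""Exception hierarchy shared across the pipeline."""


class HolopairError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HolopairError):
    """A file does not conform to the expected dialect (missing column,
    bad enum value, malformed module grammar, ...)."""


class PairingError(HolopairError):
    """The paired study design is violated: a pair id without exactly one
    host-associated and one free-living genome, or a genus mismatch."""


class ValidationError(HolopairError):
    """A record is internally inconsistent (e.g. a MAG without quality
    fields, a value outside its documented range)."""


class DesignError(HolopairError):
    """A statistical design requirement is not met (unbalanced genus,
    group with fewer than two members, unequal group sizes)."""


class UnknownGenomeError(HolopairError):
    """A table references a genome id absent from the metadata."""


class DegenerateOutputError(HolopairError):
    """An operation produced an empty or otherwise unusable result
    (e.g. zero-variance filtering removed every module)."""


class InputError(HolopairError):
    """A scalar argument is outside its domain (negative count,
    probability outside [0,1], empty sequence file)."""
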