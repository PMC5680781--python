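"""Exception hierarchy shared by all sbrt4d modules."""


class Sbrt4dError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(Sbrt4dError, ValueError):
    """A configuration value violates its invariants."""


class GeometryError(Sbrt4dError, ValueError):
    """Grids do not match, or an object does not fit on its grid."""


class EmptyStructureError(Sbrt4dError, ValueError):
    """An operation that needs occupied voxels received an empty mask."""


class DomainError(Sbrt4dError, ValueError):
    """A numeric argument is outside the operation's domain."""


class DegeneratePlanError(Sbrt4dError, ValueError):
    """A treatment plan has no open aperture at any angle."""


class NormalizationError(Sbrt4dError, ValueError):
    """Prescription normalization is impossible (zero dose in target)."""


class UndefinedStatisticError(Sbrt4dError, ValueError):
    """A statistical test is undefined for the given input (e.g. all-zero
    paired differences, constant correlation input)."""


class FixtureCorruptionError(Sbrt4dError, RuntimeError):
    """The packaged cohort fixture failed its checksum."""
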