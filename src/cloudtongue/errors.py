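"""Exception types shared across the package."""


class CloudTongueError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(CloudTongueError, ValueError):
    """A configuration object violates its invariants."""


class InvalidValueError(CloudTongueError, ValueError):
    """An input value is non-finite or otherwise out of domain."""


class InsufficientDataError(CloudTongueError, ValueError):
    """Too few samples for the requested estimate."""


class DegenerateDataError(CloudTongueError, ValueError):
    """Input carries no variance (or zero entropy) where spread is required."""


class StratificationError(CloudTongueError, ValueError):
    """A class has fewer members than the requested number of CV folds."""


class RegistryError(CloudTongueError, KeyError):
    """A predicted label has no entry in the flavor-model registry."""


class RegionConstructionError(CloudTongueError, ValueError):
    """A region set cannot be built from the supplied geometry."""
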