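"""Exception types raised across the package."""


class PatchScreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PatchScreenError, ValueError):
    """An input array, patch or parameter violates a precondition."""


class TilingError(PatchScreenError, ValueError):
    """A patch size does not tile the image exactly."""


class ConfigurationError(PatchScreenError, ValueError):
    """A pipeline or module configuration is internally inconsistent."""


class UndefinedSimilarityError(PatchScreenError, ValueError):
    """A similarity is undefined for the given vectors (e.g. zero norm)."""
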