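"""Exception types shared across the package."""


class BubbleflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigurationError(BubbleflowError, ValueError):
    """A configuration object (scene, filter spec, geometry, ...) is inconsistent."""


class InvalidInputError(BubbleflowError, ValueError):
    """A data input (stack, mask, curve, image) violates a precondition."""
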