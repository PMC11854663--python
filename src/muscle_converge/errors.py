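"""Exception types shared across the package."""


class FormatError(ValueError):
    """Malformed input file. Message carries the file position when known."""


class ConfigError(ValueError):
    """Invalid configuration or parameter value."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and its inputs."""
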