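"""Exception types raised by the simulator."""


class ParameterError(ValueError):
    """Invalid or inconsistent model parameters; message names the field."""


class ExtinctionError(RuntimeError):
    """All individuals have zero fitness: the population cannot reproduce.

    Raised by the selection step and propagated with the replicate id
    attached so sweeps can flag the outcome instead of crashing.
    """

    def __init__(self, message: str = "population extinct: all fitness values are zero",
                 generation: int | None = None, replicate: int | None = None):
        super().__init__(message)
        self.generation = generation
        self.replicate = replicate
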