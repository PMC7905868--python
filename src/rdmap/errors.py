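"""Exception hierarchy shared across the package."""


class RDmapError(Exception):
    """Base class for all rdmap errors."""


class InputError(RDmapError):
    """A file could not be read or parsed."""


class ValidationError(RDmapError):
    """Input parsed but violates a structural contract (cycle, duplicate id, ...)."""


class UnknownTermError(RDmapError, KeyError):
    """A term id does not resolve (directly or via alias) in the ontology."""

    def __init__(self, term_id: str, ontology: str = "ontology"):
        self.term_id = term_id
        super().__init__(f"unknown term id {term_id!r} in {ontology}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class ObsoleteTermError(RDmapError):
    """A query referenced a term marked obsolete in the loaded ontology."""

    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"term {term_id!r} is obsolete in the loaded ontology")
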