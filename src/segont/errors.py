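"""Exception hierarchy shared across the package."""


class SegontError(Exception):
    """Base class for all package-specific errors."""


class MissingSeedClassError(SegontError):
    """Segmentation was requested without at least one seed of each class."""

    def __init__(self, missing: str):
        self.missing = missing
        super().__init__(f"no {missing} seeds present; at least one is required")


class SeedConflictError(SegontError):
    """A pixel was given contradictory foreground/background labels."""

    def __init__(self, pixel: tuple[int, int]):
        self.pixel = pixel
        super().__init__(
            f"pixel {pixel} is already seeded with the opposite class; "
            "clear seeds before relabeling"
        )


class ShapeMismatchError(SegontError):
    """Two per-pixel structures do not share the same lattice shape."""


class ValidationError(SegontError):
    """A document or archive violates one or more structural invariants."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))


class ArchiveFormatError(SegontError):
    """An archive is missing entries or is internally inconsistent."""


class UnsupportedVersionError(ArchiveFormatError):
    """The archive declares a format version newer than this reader supports."""


class ProviderUnavailableError(SegontError):
    """An ontology or taxon provider cannot serve requests (distinct from no matches)."""


class TermNotFoundError(SegontError):
    """A well-formed term identifier is absent from the ontology source."""


class MalformedCurieError(SegontError):
    """A term identifier does not match the PREFIX:digits CURIE pattern."""
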