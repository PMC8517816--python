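#!/usr/bin/env python
"""Regenerate the packaged default model document from the recipe in
``companionbn.builtin``. Run from the repository root after editing the
elicited tables or the placeholder recipe."""

from companionbn.builtin import build_default_model, default_model_path
from companionbn.io import load_model, save_model


def main() -> None:
    model = build_default_model()
    path = default_model_path()
    save_model(model, path)
    assert load_model(path) == model, "round-trip mismatch after regeneration"
    print(f"wrote {path}: {len(model.dimensions)} dimensions, "
          f"{len(model.questions)} questions, {len(model.advice)} advice")


if __name__ == "__main__":
    main()
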