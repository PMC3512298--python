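"""Regenerate the shipped basic-unit template data file.

Usage: python scripts/make_template.py
Writes src/micromyo/data/basic_unit.json (deterministic).
"""

from pathlib import Path

from micromyo._template_builder import build_template, template_to_json

out = Path(__file__).resolve().parents[1] / "src" / "micromyo" / "data" / "basic_unit.json"
out.parent.mkdir(parents=True, exist_ok=True)
out.write_text(template_to_json(build_template()))
print(f"wrote {out}")
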