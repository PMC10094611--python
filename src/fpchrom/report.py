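"""Photophysics arithmetic and the config-driven report runner.

Brightness of a fluorescent protein is proportional to the product of its
molar extinction coefficient (EC, M⁻¹·cm⁻¹) and fluorescence quantum yield
(FQY); relative brightness compares that product against a reference
protein, reported as an integer percent.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

from . import __version__


@dataclass
class SpectralRecord:
    """Photophysical summary of one fluorescent protein."""

    name: str
    lambda_ex: float        # nm
    lambda_em: float        # nm
    ec: float               # M⁻¹·cm⁻¹
    fqy: float              # photons emitted / photons absorbed
    fl: float = 0.0         # fluorescence lifetime, ns

    def __post_init__(self) -> None:
        if self.ec <= 0:
            raise ValueError("extinction coefficient must be positive")
        if not 0.0 <= self.fqy <= 1.0:
            raise ValueError("quantum yield must be in [0, 1]")


def relative_brightness(x: SpectralRecord, reference: SpectralRecord) -> int:
    """Brightness of ``x`` relative to ``reference``: 100·(EC·FQY)ₓ/(EC·FQY)ᵣ,
    rounded to integer percent."""
    denom = reference.ec * reference.fqy
    if denom <= 0:
        raise ValueError("reference EC·FQY must be positive")
    return round(100.0 * (x.ec * x.fqy) / denom)


class ConfigError(ValueError):
    pass


def _reproducibility_header(params: dict) -> str:
    body = json.dumps({"fpchrom": __version__, **params}, sort_keys=True)
    return f"# fpchrom report {body}\n"


def run_report(config: dict, out_dir: str | Path, log=sys.stderr) -> list[Path]:
    """Execute the analysis blocks named in ``config`` and write TSV/JSON.

    Recognized blocks: ``shell`` (static census), ``brightness``,
    ``simulate`` (synthetic ensemble + manifest).  Every output carries a
    reproducibility header with the parameter set that produced it.
    Unknown blocks raise :class:`ConfigError`.
    """
    from . import contacts as _contacts
    from . import synthetic_data as _syn
    from .structure_io import identify_chromophore, parse_pdb, write_pdb, write_ensemble_xyz

    known = {"shell", "brightness", "simulate"}
    blocks = {k: v for k, v in config.items() if k != "meta"}
    if not blocks:
        raise ConfigError("config names no analysis blocks")
    unknown = set(blocks) - known
    if unknown:
        raise ConfigError(f"unknown config blocks: {sorted(unknown)} (known: {sorted(known)})")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "shell" in blocks:
        cfg = blocks["shell"]
        text = Path(cfg["pdb"]).read_text()
        s = parse_pdb(text)
        chrom = identify_chromophore(s, cfg.get("chain", s.chain_ids()[0]))
        report = _contacts.shell_census(
            s, chrom,
            radius=cfg.get("radius", 4.0),
            hbond_cutoff=cfg.get("hbond_cutoff", 3.3),
            hydrophobic_cutoff=cfg.get("hydrophobic_cutoff", 4.0),
        )
        path = out_dir / "shell_contacts.tsv"
        path.write_text(_reproducibility_header(cfg) + _contacts.contacts_to_tsv(report.contacts))
        written.append(path)
        summary = out_dir / "shell_summary.json"
        summary.write_text(json.dumps({
            "params": cfg,
            "n_shell": len(report.shell_residues),
            "shell": [str(r) for r in report.shell_residues],
            "direct_hbond": [str(r) for r in report.direct_hbond_residues],
            "water_mediated": [str(r) for r in report.water_mediated_residues],
            "hydrophobic": [str(r) for r in report.hydrophobic_residues],
            "unclassified": [str(r) for r in report.unclassified],
        }, indent=1))
        written.append(summary)
        print(f"shell: {len(report.shell_residues)} residues -> {path}", file=log)

    if "brightness" in blocks:
        cfg = blocks["brightness"]
        probe = SpectralRecord(**cfg["protein"])
        ref = SpectralRecord(**cfg["reference"])
        rb = relative_brightness(probe, ref)
        path = out_dir / "brightness.json"
        path.write_text(json.dumps({
            "params": {"protein": asdict(probe), "reference": asdict(ref)},
            "relative_brightness_percent": rb,
        }, indent=1))
        written.append(path)
        print(f"brightness: {probe.name} vs {ref.name} = {rb}%", file=log)

    if "simulate" in blocks:
        cfg = blocks["simulate"]
        spec = _syn.GeneratorSpec(
            seed=cfg.get("seed", 0),
            n_frames=cfg.get("n_frames", 750),
            dt=cfg.get("dt", 100.0),
            sigma=cfg.get("sigma", 0.10),
        )
        base, manifest = _syn.make_toy_structure(spec)
        ens, manifest = _syn.make_ensemble(base, spec, manifest)
        prefix = cfg.get("prefix", "toy")
        p_pdb = out_dir / f"{prefix}_topology.pdb"
        p_xyz = out_dir / f"{prefix}_frames.xyz"
        p_man = out_dir / f"{prefix}_manifest.json"
        p_pdb.write_text(write_pdb(base))
        p_xyz.write_text(write_ensemble_xyz(ens))
        p_man.write_text(manifest.to_json())
        written.extend([p_pdb, p_xyz, p_man])
        print(f"simulate: {ens.n_frames} frames -> {p_xyz}", file=log)

    return written
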