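"""Output writers: legacy-VTK and PLY meshes, CSV trajectories, HDF5 fields.

Both mesh formats are plain ASCII; the beat-induced node velocity is stored
as a named vector field (``POINT_DATA`` in VTK, per-vertex ``vx vy vz``
properties in PLY).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = [
    "write_vtk",
    "write_ply",
    "write_trajectory_csv",
    "write_trajectory_h5",
    "save_phase_field",
    "load_phase_field",
]


def write_vtk(mesh, path, field_name: str = "beat_velocity") -> None:
    """Legacy ASCII VTK PolyData with per-node velocity vectors."""
    p = Path(path)
    n = len(mesh.nodes)
    lines = [
        "# vtk DataFile Version 3.0",
        "shearswim surface mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [" ".join(f"{c:.10g}" for c in row) for row in mesh.nodes]
    m = len(mesh.triangles)
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in mesh.triangles]
    lines.append(f"POINT_DATA {n}")
    lines.append(f"VECTORS {field_name} double")
    lines += [" ".join(f"{c:.10g}" for c in row) for row in mesh.node_velocities]
    p.write_text("\n".join(lines) + "\n")


def write_ply(mesh, path) -> None:
    """ASCII PLY with vertex velocity properties vx, vy, vz."""
    p = Path(path)
    n, m = len(mesh.nodes), len(mesh.triangles)
    header = [
        "ply",
        "format ascii 1.0",
        "comment shearswim surface mesh",
        f"element vertex {n}",
        "property double x",
        "property double y",
        "property double z",
        "property double vx",
        "property double vy",
        "property double vz",
        f"element face {m}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    body = [
        " ".join(f"{c:.10g}" for c in np.concatenate([xyz, vel]))
        for xyz, vel in zip(mesh.nodes, mesh.node_velocities)
    ]
    body += ["3 " + " ".join(str(i) for i in tri) for tri in mesh.triangles]
    p.write_text("\n".join(header + body) + "\n")


def write_trajectory_csv(traj, path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def write_trajectory_h5(traj, path) -> None:
    """HDF5 trajectory store for long runs."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=traj.times)
        f.create_dataset("x0", data=traj.positions)
        f.create_dataset("quaternion", data=traj.quaternions)
        f.create_dataset("U", data=traj.velocities)
        f.create_dataset("Omega", data=traj.angular_velocities)
        f.create_dataset("wall_clearance", data=traj.clearances)
        f.attrs["halt_reason"] = traj.halt_reason


def save_phase_field(field, path) -> None:
    """HDF5 serialization of a wall phase field with its grid metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("theta_grid", data=field.theta_grid)
        f.create_dataset("h_grid", data=field.h_grid)
        for name in ("U_beat", "W_beat", "U_shear", "W_shear"):
            f.create_dataset(name, data=getattr(field, name))
        f.create_dataset("valid", data=field.valid)
        f.attrs["n_phases"] = field.n_phases
        f.attrs["refinement"] = field.refinement
        for k, v in vars(field.config).items():
            f.attrs[f"config_{k}"] = v


def load_phase_field(path):
    import h5py

    from .geometry import SwimmerConfig
    from .phase import PhaseField

    with h5py.File(path, "r") as f:
        cfg_kwargs = {
            k[len("config_") :]: (v.item() if hasattr(v, "item") else v)
            for k, v in f.attrs.items()
            if k.startswith("config_")
        }
        if "beat_direction" in cfg_kwargs and isinstance(cfg_kwargs["beat_direction"], bytes):
            cfg_kwargs["beat_direction"] = cfg_kwargs["beat_direction"].decode()
        return PhaseField(
            theta_grid=f["theta_grid"][:],
            h_grid=f["h_grid"][:],
            U_beat=f["U_beat"][:],
            W_beat=f["W_beat"][:],
            U_shear=f["U_shear"][:],
            W_shear=f["W_shear"][:],
            valid=f["valid"][:].astype(bool),
            n_phases=int(f.attrs["n_phases"]),
            refinement=int(f.attrs["refinement"]),
            config=SwimmerConfig(**cfg_kwargs),
        )
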