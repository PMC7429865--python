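#!/usr/bin/env python
"""Derive the theoretical astronaut populations (crew characteristics).

Five statures spanning the agency band (1.50-1.90 m), shared BMI
26.5 kg/m^2 and age 40 y, give body masses of 59.6-95.7 kg, surface
areas of 1.54-2.24 m^2 and absolute VO2max of 2.59-4.15 L/min.  Resting
metabolism (Harris-Benedict RMR 5.78-8.60 MJ/d) and 75%-VO2max exercise
rates (EE 9.6-15.4 kcal/min, heat 667-1,070 J/s) scale accordingly.

Writes results/table1.csv.
"""

from pathlib import Path

from crewmet.tables import table1

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    df = table1()
    df.to_csv(OUT / "table1.csv")
    print("Crew characteristics by stature (m):")
    print(df.to_string())
    print(f"\nwrote {OUT / 'table1.csv'}")


if __name__ == "__main__":
    main()
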