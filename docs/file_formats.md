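# File formats

All tables are comma-separated UTF-8 with a mandatory header row and
decimal points. Missing optional numeric cells are empty strings ("NA" is
also accepted on read). These layouts are this package's own — surveys of
this kind do not publish a raw-table schema.

## Specimen table (`io.read_specimen_table` / `write_specimen_table`)

| column          | type            | notes                                   |
|-----------------|-----------------|-----------------------------------------|
| id              | text, unique    | specimen identifier                     |
| species         | text            | scientific name                         |
| season          | `rainy` / `dry` | case-insensitive                        |
| length_cm       | positive real   | total length L                          |
| weight_g        | positive real   | total weight W                          |
| liver_weight_g  | real ≥ 0, opt.  | LW; must not exceed weight_g            |
| parasite_count  | integer ≥ 0     | larval nematodes found in the specimen  |
| thg_ugg         | real ≥ 0, opt.  | muscle T-Hg, µg/g wet weight            |
| trophic_level   | real in [2, 5]  | from a fish-ecology reference database  |

Malformed rows are never dropped silently: reading fails with the 1-based
data row number and offending column.

## Histology table (`io.read_histology_table`)

`specimen_id`, `species`, then one integer 0–3 column per lesion category:
`ST, LY, MM, FB, HH, NH, NC, AP, HC, BC` (steatosis, lymphocytic
infiltrates, melanomacrophage inflammation, vessel fibrosis, hepatocyte
hypertrophy, nuclear hypertrophy, necrosis, apoptosis, hepatic congestion,
blood congestion).

## QC table (`io.read_qc_table`)

| column    | notes                                                        |
|-----------|--------------------------------------------------------------|
| kind      | `blank`, `crm`, `sample`, or `calibration`                   |
| sample_id | groups duplicate `sample` readings                           |
| value     | measured concentration, µg/g                                 |
| reference | certified value (`crm`) or nominal level (`calibration`)     |

## FASTA

Pre-aligned sequences over `A C G T N -`; equal lengths enforced, input
uppercased, written at 70 columns/line.

## Newick

Standard newick with branch lengths; integer bootstrap percentages appear
as internal-node labels; terminated by `;`.
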