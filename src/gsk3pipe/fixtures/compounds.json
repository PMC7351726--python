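[
 {
  "id": "1",
  "role": "parent",
  "formula": "C16H10N2O2",
  "graph_ref": "1"
 },
 {
  "id": "2",
  "role": "parent",
  "formula": "C16H11N3O2",
  "graph_ref": "2"
 },
 {
  "id": "3",
  "role": "intermediate",
  "formula": "C19H12N2O2",
  "graph_ref": "3"
 },
 {
  "id": "4",
  "role": "intermediate",
  "formula": "C19H13N3O2",
  "graph_ref": "4"
 },
 {
  "id": "6a",
  "role": "designed"
 },
 {
  "id": "6b",
  "role": "designed"
 },
 {
  "id": "6c",
  "role": "designed"
 },
 {
  "id": "6d",
  "role": "designed"
 },
 {
  "id": "6e",
  "role": "designed"
 },
 {
  "id": "6f",
  "role": "designed"
 },
 {
  "id": "6g",
  "role": "designed"
 },
 {
  "id": "6h",
  "role": "designed"
 },
 {
  "id": "6i",
  "role": "designed"
 },
 {
  "id": "6k",
  "role": "designed"
 },
 {
  "id": "6l",
  "role": "designed"
 },
 {
  "id": "6m",
  "role": "designed"
 },
 {
  "id": "6n",
  "role": "designed"
 },
 {
  "id": "6o",
  "role": "designed"
 },
 {
  "id": "6p",
  "role": "designed"
 },
 {
  "id": "CHIR-98014",
  "role": "reference-inhibitor"
 },
 {
  "id": "Bio-acetoxime",
  "role": "reference-inhibitor"
 },
 {
  "id": "Ellipticine",
  "role": "reference-drug"
 }
]
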