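{
 "reference_id": "REF901",
 "assays": [
  {
   "id": "KMR019",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR020",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR021",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR022",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR023",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR024",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR025",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR026",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR027",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR028",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR029",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR030",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR031",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR032",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR033",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR034",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR035",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR036",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR037",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR038",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR039",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR040",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR041",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR042",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR043",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR044",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR045",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR046",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR047",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR048",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR049",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR050",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR051",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR052",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR053",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR054",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR055",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR056",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  },
  {
   "id": "KMR057",
   "allele_freq": 0.25,
   "cq_window": [
    15.0,
    38.0
   ],
   "positive_dcq_max": 3.0,
   "negative_dcq_min": 6.0
  }
 ]
}
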