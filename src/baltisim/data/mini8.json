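{
 "schema_version": 1,
 "layers": {
  "interface_depths": [
   10.0,
   25.0,
   60.0
  ],
  "sediment_thickness": 0.5
 },
 "boxes": [
  {
   "box_id": 0,
   "vertices": [
    [
     10.0,
     54.0
    ],
    [
     11.0,
     54.0
    ],
    [
     11.0,
     55.0
    ],
    [
     10.0,
     55.0
    ]
   ],
   "area": 10000000000.0,
   "max_depth": 60.0,
   "kind": "boundary",
   "habitat_cover": {
    "mud": 1.0
   },
   "region": "north_sea",
   "coastal": false,
   "axis": 0.0
  },
  {
   "box_id": 1,
   "vertices": [
    [
     11.0,
     55.0
    ],
    [
     12.0,
     55.0
    ],
    [
     12.0,
     56.0
    ],
    [
     11.0,
     56.0
    ]
   ],
   "area": 2000000000.0,
   "max_depth": 32.0,
   "kind": "dynamic",
   "habitat_cover": {
    "bedrock": 0.15,
    "sand": 0.5,
    "mud": 0.3,
    "man-made": 0.05
   },
   "region": "kattegat",
   "coastal": true,
   "axis": 0.1
  },
  {
   "box_id": 2,
   "vertices": [
    [
     12.0,
     54.0
    ],
    [
     13.0,
     54.0
    ],
    [
     13.0,
     55.0
    ],
    [
     12.0,
     55.0
    ]
   ],
   "area": 8000000000.0,
   "max_depth": 60.0,
   "kind": "dynamic",
   "habitat_cover": {
    "sand": 0.2,
    "mud": 0.8
   },
   "region": "kattegat",
   "coastal": false,
   "axis": 0.2
  },
  {
   "box_id": 3,
   "vertices": [
    [
     13.0,
     55.0
    ],
    [
     14.0,
     55.0
    ],
    [
     14.0,
     56.0
    ],
    [
     13.0,
     56.0
    ]
   ],
   "area": 2000000000.0,
   "max_depth": 34.0,
   "kind": "dynamic",
   "habitat_cover": {
    "bedrock": 0.15,
    "sand": 0.5,
    "mud": 0.3,
    "man-made": 0.05
   },
   "region": "western_baltic",
   "coastal": true,
   "axis": 0.35
  },
  {
   "box_id": 4,
   "vertices": [
    [
     14.0,
     54.0
    ],
    [
     15.0,
     54.0
    ],
    [
     15.0,
     55.0
    ],
    [
     14.0,
     55.0
    ]
   ],
   "area": 10000000000.0,
   "max_depth": 60.0,
   "kind": "dynamic",
   "habitat_cover": {
    "sand": 0.2,
    "mud": 0.8
   },
   "region": "western_baltic",
   "coastal": false,
   "axis": 0.45
  },
  {
   "box_id": 5,
   "vertices": [
    [
     15.0,
     55.0
    ],
    [
     16.0,
     55.0
    ],
    [
     16.0,
     56.0
    ],
    [
     15.0,
     56.0
    ]
   ],
   "area": 2500000000.0,
   "max_depth": 30.0,
   "kind": "dynamic",
   "habitat_cover": {
    "bedrock": 0.15,
    "sand": 0.5,
    "mud": 0.3,
    "man-made": 0.05
   },
   "region": "baltic_proper",
   "coastal": true,
   "axis": 0.6
  },
  {
   "box_id": 6,
   "vertices": [
    [
     16.0,
     54.0
    ],
    [
     17.0,
     54.0
    ],
    [
     17.0,
     55.0
    ],
    [
     16.0,
     55.0
    ]
   ],
   "area": 15000000000.0,
   "max_depth": 60.0,
   "kind": "dynamic",
   "habitat_cover": {
    "mud": 1.0
   },
   "region": "baltic_proper",
   "coastal": false,
   "axis": 0.75
  },
  {
   "box_id": 7,
   "vertices": [
    [
     17.0,
     55.0
    ],
    [
     18.0,
     55.0
    ],
    [
     18.0,
     56.0
    ],
    [
     17.0,
     56.0
    ]
   ],
   "area": 12000000000.0,
   "max_depth": 60.0,
   "kind": "dynamic",
   "habitat_cover": {
    "mud": 1.0
   },
   "region": "baltic_proper",
   "coastal": false,
   "axis": 0.95
  }
 ],
 "faces": [
  {
   "face_id": 0,
   "left_box": 0,
   "right_box": 1,
   "length": 20000.0
  },
  {
   "face_id": 1,
   "left_box": 0,
   "right_box": 2,
   "length": 20000.0
  },
  {
   "face_id": 2,
   "left_box": 1,
   "right_box": 2,
   "length": 20000.0
  },
  {
   "face_id": 3,
   "left_box": 1,
   "right_box": 3,
   "length": 20000.0
  },
  {
   "face_id": 4,
   "left_box": 2,
   "right_box": 4,
   "length": 20000.0
  },
  {
   "face_id": 5,
   "left_box": 3,
   "right_box": 4,
   "length": 20000.0
  },
  {
   "face_id": 6,
   "left_box": 3,
   "right_box": 5,
   "length": 20000.0
  },
  {
   "face_id": 7,
   "left_box": 4,
   "right_box": 5,
   "length": 20000.0
  },
  {
   "face_id": 8,
   "left_box": 4,
   "right_box": 6,
   "length": 20000.0
  },
  {
   "face_id": 9,
   "left_box": 5,
   "right_box": 6,
   "length": 20000.0
  },
  {
   "face_id": 10,
   "left_box": 6,
   "right_box": 7,
   "length": 20000.0
  },
  {
   "face_id": 11,
   "left_box": 4,
   "right_box": 7,
   "length": 20000.0
  },
  {
   "face_id": 12,
   "left_box": 0,
   "right_box": 7,
   "length": 20000.0
  }
 ]
}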