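{
 "$id": "baltisim-geometry",
 "version": 1,
 "description": "Box-model geometry: polygons, faces, vertical layers, habitat cover",
 "type": "object",
 "required": [
  "schema_version",
  "layers",
  "boxes",
  "faces"
 ],
 "properties": {
  "schema_version": {
   "type": "integer"
  },
  "layers": {
   "type": "object",
   "required": [
    "interface_depths"
   ],
   "properties": {
    "interface_depths": {
     "type": "array",
     "items": {
      "type": "number"
     },
     "description": "strictly increasing water-layer bottom depths (m)"
    },
    "sediment_thickness": {
     "type": "number",
     "default": 0.5
    }
   }
  },
  "boxes": {
   "type": "array",
   "items": {
    "type": "object",
    "required": [
     "box_id",
     "vertices",
     "area",
     "max_depth",
     "kind",
     "habitat_cover"
    ],
    "properties": {
     "box_id": {
      "type": "integer",
      "description": "contiguous from 0"
     },
     "vertices": {
      "type": "array",
      "items": {
       "type": "array"
      },
      "description": "(lon, lat) degrees, counter-clockwise"
     },
     "area": {
      "type": "number",
      "description": "m2 (taken as given, not recomputed)"
     },
     "max_depth": {
      "type": "number",
      "description": "m"
     },
     "kind": {
      "enum": [
       "dynamic",
       "boundary"
      ]
     },
     "habitat_cover": {
      "type": "object",
      "description": "bedrock/sand/mud/man-made fractions summing to 1"
     },
     "region": {
      "type": "string"
     },
     "coastal": {
      "type": "boolean"
     },
     "axis": {
      "type": "number",
      "description": "position on the Kattegat->Bothnian axis in [0,1]"
     }
    }
   }
  },
  "faces": {
   "type": "array",
   "items": {
    "type": "object",
    "required": [
     "face_id",
     "left_box",
     "right_box",
     "length"
    ],
    "properties": {
     "face_id": {
      "type": "integer"
     },
     "left_box": {
      "type": "integer"
     },
     "right_box": {
      "type": "integer"
     },
     "length": {
      "type": "number",
      "description": "m"
     }
    }
   }
  }
 }
}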