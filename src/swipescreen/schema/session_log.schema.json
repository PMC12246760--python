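{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/swipescreen/session_log.schema.json",
  "title": "Swipe-gesture game session log",
  "description": "One participant x game play session: per-swipe gesture events (Table-3 style field names) plus columnar accelerometer/gyroscope streams. Coordinates are screen px with origin at the bottom-left of the screen in the session's orientation; times are seconds. swipe_event_time is anchored at game launch, swipe_start_time/swipe_end_time at the most recent level load.",
  "type": "object",
  "required": ["participant_id", "game", "orientation", "screen_dims", "session_limit", "gameplay_window", "swipes", "sensors"],
  "properties": {
    "participant_id": {"type": "string", "minLength": 1},
    "game": {"enum": ["puzzle", "runner", "slicer"]},
    "orientation": {"enum": ["landscape", "portrait"]},
    "screen_dims": {
      "type": "array", "items": {"type": "integer", "minimum": 1},
      "minItems": 2, "maxItems": 2,
      "description": "[width_px, height_px]"
    },
    "session_limit": {"type": "number", "minimum": 0},
    "gameplay_window": {
      "type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2,
      "description": "[start_s, end_s] of actual gameplay in launch-anchored time; swipes outside are menu interactions"
    },
    "swipes": {"type": "array", "items": {"$ref": "#/definitions/swipe"}},
    "sensors": {"type": "array", "items": {"$ref": "#/definitions/sensor_stream"}}
  },
  "definitions": {
    "swipe": {
      "type": "object",
      "required": ["swipe_ID", "swipe_event_time", "swipe_start_time", "swipe_end_time", "swipe_start_pos", "swipe_end_pos", "swipe_pos", "swipe_start_press", "swipe_end_press", "swipe_start_press_variance", "swipe_end_press_variance", "swipe_press", "swipe_press_variance", "swipe_speed", "swipe_duration", "swipe_distance", "swipe_direction", "time_between_swipes"],
      "properties": {
        "swipe_ID": {"type": "integer"},
        "swipe_event_time": {"type": "number", "minimum": 0},
        "swipe_start_time": {"type": "number", "minimum": 0},
        "swipe_end_time": {"type": "number", "minimum": 0},
        "swipe_start_pos": {"$ref": "#/definitions/xy"},
        "swipe_end_pos": {"$ref": "#/definitions/xy"},
        "swipe_pos": {
          "type": "array", "minItems": 2,
          "items": {"type": "array", "items": {"type": "number"}, "minItems": 4, "maxItems": 4},
          "description": "ordered touch path rows [t_since_swipe_start_s, x_px, y_px, press]"
        },
        "swipe_start_press": {"$ref": "#/definitions/press"},
        "swipe_end_press": {"$ref": "#/definitions/press"},
        "swipe_start_press_variance": {"type": "number", "minimum": 0},
        "swipe_end_press_variance": {"type": "number", "minimum": 0},
        "swipe_press": {"$ref": "#/definitions/press"},
        "swipe_press_variance": {"type": "number", "minimum": 0},
        "swipe_speed": {"type": "number", "minimum": 0},
        "swipe_duration": {"type": "number", "minimum": 0},
        "swipe_distance": {"type": "number", "minimum": 0},
        "swipe_direction": {
          "enum": ["up", "down", "left", "right", "none"],
          "description": "dominant-axis direction; 'none' for the slicer game, where direction is not computed"
        },
        "time_between_swipes": {
          "type": ["number", "null"],
          "description": "seconds since the previous swipe ended; null for the first swipe"
        }
      }
    },
    "sensor_stream": {
      "type": "object",
      "required": ["stream", "t", "x", "y", "z"],
      "properties": {
        "stream": {"enum": ["accelerometer", "gyroscope"]},
        "t": {"type": "array", "items": {"type": "number", "minimum": 0}},
        "x": {"type": "array", "items": {"type": "number"}},
        "y": {"type": "array", "items": {"type": "number"}},
        "z": {"type": "array", "items": {"type": "number"}}
      },
      "description": "columnar stream sampled independently of swipe events; axis units m/s^2 (accelerometer) or rad/s (gyroscope)"
    },
    "xy": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
    "press": {"type": "number", "minimum": 0, "maximum": 1, "description": "contact-area pressure proxy, dimensionless in [0, 1]"}
  }
}
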